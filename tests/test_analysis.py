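"""NMR identification, co-solvent selection, trend fitting, class audits."""

import numpy as np
import pytest

from specieskg.analysis import (
    ClassRule,
    ObservedPeak,
    check_class_consistency,
    extrapolate_bp,
    filter_nmr_candidates,
    find_missing_class_tags,
    fit_cube_root,
    identify_mixture,
    load_class_rules,
    match_species_to_spectrum,
    prune_minor_peaks,
    refine_by_multiplicity,
    select_cosolvents,
    trend_points,
)
from specieskg.fixtures import (
    FixtureSpec,
    catholyte_observed_peaks,
    gen_mixture_spectrum,
    gen_species_library,
    mixture_demo_library,
)
from specieskg.ingest import InMemoryProvider, ingest_species
from specieskg.model import (
    EmpiricalFormula,
    Peak,
    count_double_bonds,
    formula_matches,
)
from specieskg.store import SpeciesStore


def build_store(seed=11, n_species=25, **kwargs):
    lib = gen_species_library(FixtureSpec(seed=seed, n_species=n_species, **kwargs))
    store = SpeciesStore()
    iris = lib.populate(store)
    return store, lib, iris


def make_species_provider(entries):
    """entries: list of (formula, tb_string or None, ghs codes, class ids)"""
    computed, annotation = {}, {}
    for i, (formula, tb, ghs, classes) in enumerate(entries):
        key = f"k{i}"
        computed[key] = {
            "identifiers": {"InChI": f"InChI=1S/{formula}/x{i}",
                            "MolecularFormula": formula},
        }
        annotation[key] = {
            "experimental_properties": (
                [{"kind": "BoilingPoint", "string": tb, "source": {"label": "s"}}]
                if tb
                else []
            ),
            "ghs": [{"code": c} for c in ghs],
            "classes": classes,
        }
    from specieskg.fixtures import SYNTHETIC_CLASS_TREE

    return InMemoryProvider(computed, annotation, classes=dict(SYNTHETIC_CLASS_TREE))


class TestNmrCandidateFilter:
    def test_formula_and_boiling_bounds(self):
        provider = make_species_provider(
            [
                ("CH2O2", "374 K", [], []),      # formic-acid-like: included
                ("C5H12O", "411 K", [], []),     # five carbons: excluded (C < 5)
                ("C2H6O", "248 K", [], []),      # too volatile: excluded
                ("C2H7N", "290 K", [], []),      # nitrogen: excluded
                ("C2H6O2", None, [], []),        # no boiling point: excluded
            ]
        )
        store = SpeciesStore()
        iris = [ingest_species(f"k{i}", provider, store) for i in range(5)]
        assert filter_nmr_candidates(store) == [iris[0]]


class TestPruneMinorPeaks:
    def test_below_20_percent_discarded(self):
        peaks = [Peak(1.0, 100.0), Peak(2.0, 15.0), Peak(3.0, 30.0)]
        kept = prune_minor_peaks(peaks)
        assert [p.intensity for p in kept] == [100.0, 30.0]

    def test_single_peak_is_its_own_max(self):
        (p,) = prune_minor_peaks([Peak(1.0, 0.5)])
        assert p.intensity == 0.5

    def test_equal_intensities_all_kept(self):
        peaks = [Peak(x, 40.0) for x in (1.0, 2.0, 3.0)]
        assert prune_minor_peaks(peaks) == peaks

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prune_minor_peaks([])


class TestStageOneMatching:
    def test_window_arithmetic(self):
        observed = [ObservedPeak(8.35, "singlet", "analyte")]
        inside = match_species_to_spectrum({"s": [Peak(8.30, 10.0)]}, observed)
        assert [m.species_iri for m in inside] == ["s"]
        outside = match_species_to_spectrum({"s": [Peak(3.20, 10.0)]},
                                            [ObservedPeak(3.51, None, "analyte")])
        assert outside == []

    def test_solvent_and_reference_roles_open_no_windows(self):
        observed = [
            ObservedPeak(4.9, "singlet", "solvent"),
            ObservedPeak(2.6, "singlet", "reference"),
        ]
        assert match_species_to_spectrum({"s": [Peak(4.9, 10.0)]}, observed) == []

    def test_demo_library_yields_exactly_the_four_components(self):
        survivors = identify_mixture(mixture_demo_library(), catholyte_observed_peaks())
        assert sorted(survivors) == [
            "acetic acid", "ethanol", "ethoxyethane", "formic acid",
        ]

    def test_window_enlargement_is_monotone(self, rng):
        """Growing the window never removes a stage-1 candidate."""
        for _ in range(60):
            library = {
                f"s{i}": [
                    Peak(round(float(rng.uniform(0, 10)), 2), 10.0)
                    for _ in range(rng.integers(1, 4))
                ]
                for i in range(6)
            }
            observed = [
                ObservedPeak(round(float(rng.uniform(0, 10)), 2), None, "analyte")
                for _ in range(rng.integers(1, 5))
            ]
            small = {m.species_iri for m in match_species_to_spectrum(library, observed, 0.2)}
            large = {m.species_iri for m in match_species_to_spectrum(library, observed, 0.5)}
            assert small <= large


class TestStageTwoRefinement:
    def test_multiplicity_mismatch_rejected(self):
        observed = [ObservedPeak(8.35, "singlet", "analyte")]
        candidates = match_species_to_spectrum(
            {"s": [Peak(8.30, 10.0, "doublet")]}, observed
        )
        assert refine_by_multiplicity(candidates, observed) == []

    def test_unknown_multiplicity_passes(self):
        observed = [ObservedPeak(8.35, "singlet", "analyte")]
        candidates = match_species_to_spectrum({"s": [Peak(8.30, 10.0, None)]}, observed)
        assert refine_by_multiplicity(candidates, observed) == ["s"]

    def test_two_library_peaks_in_one_window_rejected(self):
        observed = [ObservedPeak(1.83, "singlet", "analyte")]
        candidates = match_species_to_spectrum(
            {"s": [Peak(1.70, 10.0, "singlet"), Peak(1.95, 9.0, "singlet")]}, observed
        )
        assert refine_by_multiplicity(candidates, observed) == []


class TestPlantedRecovery:
    def test_planted_species_always_stage_one_candidates(self):
        """100 random planted mixtures: every planted species is recovered
        among the stage-1 candidates (jitter stays below window/2)."""
        for seed in range(100):
            spec = FixtureSpec(seed=seed, n_species=12, nmr_rate=1.0)
            lib = gen_species_library(spec)
            library = lib.peak_library()
            rng = np.random.default_rng(seed)
            labels = sorted(library)
            planted = list(
                rng.choice(labels, size=min(3, len(labels)), replace=False)
            )
            observed = gen_mixture_spectrum(library, planted, spec)
            stage1 = {
                m.species_iri
                for m in match_species_to_spectrum(
                    {k: prune_minor_peaks(v) for k, v in library.items()}, observed
                )
            }
            assert set(planted) <= stage1


class TestCosolventSelection:
    def entries(self):
        return [
            ("C3H8O", "355.4 K", [], ["cls:alkanol"]),        # reference
            ("C4H10O", "368 K", [], ["cls:alkanol"]),         # Δ=12.6 < 15: out
            ("C5H12O", "411 K", [], ["cls:alkanol"]),         # in
            ("C6H14O", "430 K", ["H350"], ["cls:alkanol"]),   # carcinogen: out
            ("C7H16O", "449 K", ["H360"], ["cls:alkanol"]),   # repro-tox: out
            ("C8H18O", "468.35 K", [], ["cls:alkanol"]),      # in unless tb_max
            ("C2H6O", "351.5 K", ["H225"], ["cls:alkanol"]),  # Δ<15: out
        ]

    @pytest.fixture()
    def solvent_store(self):
        provider = make_species_provider(self.entries())
        store = SpeciesStore()
        iris = [ingest_species(f"k{i}", provider, store) for i in range(7)]
        return store, iris

    def test_criteria(self, solvent_store):
        store, iris = solvent_store
        selected = select_cosolvents(store, iris[0], "alcohol")
        assert selected == sorted([iris[2], iris[5]])

    def test_boiling_ceiling(self, solvent_store):
        store, iris = solvent_store
        selected = select_cosolvents(store, iris[0], "alcohol", tb_max_K=423.15)
        assert selected == [iris[2]]

    def test_delta_criterion_symmetry(self, solvent_store):
        store, iris = solvent_store

        def tb(iri):
            from specieskg.analysis import recommended_value

            return recommended_value(store, iri, "BoilingPoint")

        for a in iris:
            for b in iris:
                if a == b:
                    continue
                assert (abs(tb(a) - tb(b)) >= 15) == (abs(tb(b) - tb(a)) >= 15)

    def test_missing_reference_boiling_point(self, solvent_store):
        store, iris = solvent_store
        provider = make_species_provider([("C9H20O", None, [], ["cls:alkanol"])])
        bare = ingest_species("k0", provider, store)
        with pytest.raises(ValueError):
            select_cosolvents(store, bare, "alcohol")


class TestCubeRootTrend:
    def test_noiseless_recovery(self):
        points = [(n, 100.0 * n ** (1 / 3) + 50.0) for n in range(1, 11)]
        fit = fit_cube_root(points)
        assert fit.a == pytest.approx(100.0, abs=1e-6)
        assert fit.b == pytest.approx(50.0, abs=1e-6)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact_interpolation(self):
        fit = fit_cube_root([(1, 150.0), (8, 250.0)])
        assert extrapolate_bp(fit, 1) == pytest.approx(150.0)
        assert extrapolate_bp(fit, 8) == pytest.approx(250.0)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        a_true, b_true = 120.0, 80.0
        n = np.arange(1, 13)
        tb = a_true * np.cbrt(n) + b_true + rng.normal(0, 2.0, size=n.size)
        fit = fit_cube_root(list(zip(n.tolist(), tb.tolist())))
        # dense grid-search least squares around the truth
        a_grid = np.linspace(a_true - 20, a_true + 20, 401)
        b_grid = np.linspace(b_true - 20, b_true + 20, 401)
        design = np.cbrt(n)[:, None, None]
        residual = (
            tb[:, None, None] - a_grid[None, :, None] * design - b_grid[None, None, :]
        )
        ss = (residual**2).sum(axis=0)
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        step_a = a_grid[1] - a_grid[0]
        step_b = b_grid[1] - b_grid[0]
        assert abs(fit.a - a_grid[i]) <= step_a
        assert abs(fit.b - b_grid[j]) <= step_b

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(1, 30, size=rng.integers(2, 10))
            if len(set(n.tolist())) < 2:
                continue
            tb = rng.uniform(100, 500, size=n.size)
            fit = fit_cube_root(list(zip(n.tolist(), tb.tolist())))
            X = np.column_stack([np.cbrt(n.astype(float)), np.ones(n.size)])
            coef = np.linalg.solve(X.T @ X, X.T @ tb)
            assert fit.a == pytest.approx(coef[0], rel=1e-9, abs=1e-9)
            assert fit.b == pytest.approx(coef[1], rel=1e-9, abs=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_cube_root([(3, 300.0), (3, 301.0)])

    def test_extrapolation_examples(self):
        fit = fit_cube_root([(1, 150.0), (8, 250.0)])
        fit100 = fit_cube_root([(n, 100.0 * n ** (1 / 3) + 50.0) for n in (1, 8)])
        assert extrapolate_bp(fit100, 8) == pytest.approx(250.0)
        assert extrapolate_bp(fit100, 1) == pytest.approx(150.0)
        values = [extrapolate_bp(fit100, k) for k in range(1, 20)]
        assert values == sorted(values)  # monotone when a > 0

    def test_trend_points_from_generated_library(self):
        store, lib, _ = build_store(seed=5, n_species=30, untagged_rate=0.0)
        points = trend_points(store, "alkane")
        truth = lib.ground_truth
        assert len(points) == int((truth.cls == "alkane").sum())


class TestClassAudits:
    def test_untagged_alkene_reported_and_tagged_not(self):
        provider = make_species_provider(
            [
                ("C5H10", None, [], []),              # alkene formula, untagged
                ("C2H4", None, [], ["cls:alkene"]),   # correctly tagged
            ]
        )
        # give both one double bond
        for key in ("k0", "k1"):
            n_c = 5 if key == "k0" else 2
            provider.computed_docs[key]["atoms"] = [
                {"index": i + 1, "element": "C"} for i in range(n_c)
            ]
            provider.computed_docs[key]["bonds"] = [
                {"atom_a": i, "atom_b": i + 1, "order": 2 if i == 1 else 1}
                for i in range(1, n_c)
            ]
        store = SpeciesStore()
        iris = [ingest_species(f"k{i}", provider, store) for i in range(2)]
        rule = load_class_rules()["alkene"]
        assert find_missing_class_tags(store, rule) == [iris[0]]

    def test_tagged_alkadiene_is_a_violation(self):
        # C20H38 with two double bonds, wrongly tagged as alkene
        provider = make_species_provider([("C20H38", None, [], ["cls:alkene"])])
        provider.computed_docs["k0"]["bonds"] = [
            {"atom_a": i, "atom_b": i + 1, "order": 2 if i in (1, 5) else 1}
            for i in range(1, 20)
        ]
        store = SpeciesStore()
        (iri,) = [ingest_species("k0", provider, store)]
        rule = load_class_rules()["alkene"]
        violations = check_class_consistency(store, rule)
        assert [v[0] for v in violations] == [iri]

    def test_correctly_tagged_ethene_clean(self):
        provider = make_species_provider([("C2H4", None, [], ["cls:alkene"])])
        provider.computed_docs["k0"]["bonds"] = [{"atom_a": 1, "atom_b": 2, "order": 2}]
        store = SpeciesStore()
        ingest_species("k0", provider, store)
        assert check_class_consistency(store, load_class_rules()["alkene"]) == []

    def test_empty_store_empty_reports(self):
        store = SpeciesStore()
        rule = load_class_rules()["alkene"]
        assert find_missing_class_tags(store, rule) == []
        assert check_class_consistency(store, rule) == []

    def test_random_library_matches_linear_scan_oracle(self):
        store, lib, iris = build_store(seed=9, n_species=40, untagged_rate=0.3)
        rule = load_class_rules()["alkene"]
        tagged = store.species_in_class("alkene")
        oracle = []
        for iri in iris:
            sp = store.load_species(iri)
            satisfies = (
                formula_matches(sp.formula, "alkene")
                and count_double_bonds(sp.bonds) == 1
            )
            if satisfies and iri not in tagged:
                oracle.append(iri)
        assert find_missing_class_tags(store, rule) == sorted(oracle)
        # the generator's assignments are consistent: no tagged violations
        assert check_class_consistency(store, rule) == []
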