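"""Independent brute-force oracles shared by the test suite."""


def brute_groups(values, rel_tol):
    """Transitive closure of pairwise relative proximity (single linkage)."""
    n = len(values)

    def close(a, b):
        lo = min(abs(a), abs(b))
        if lo == 0:
            return a == b
        return abs(a - b) / lo <= rel_tol

    adjacent = [[close(values[i], values[j]) for j in range(n)] for i in range(n)]
    groups, unassigned = [], set(range(n))
    while unassigned:
        seed = min(unassigned)
        component, frontier = {seed}, {seed}
        while frontier:
            nxt = {
                j
                for i in frontier
                for j in range(n)
                if adjacent[i][j] and j not in component
            }
            component |= nxt
            frontier = nxt
        groups.append(frozenset(component))
        unassigned -= component
    return set(groups)
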