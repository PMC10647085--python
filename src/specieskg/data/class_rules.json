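{
  "alkane": {"formula_pattern": "alkane"},
  "alkene": {"formula_pattern": "alkene", "double_bond_count": 1},
  "alkanol": {"formula_pattern": "alkanol"}
}
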