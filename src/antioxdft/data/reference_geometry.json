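{
  "comment": "Reference geometric/topological values for luteolin at M06-2X/6-311++G(d,p): the intramolecular O1-H...O=C hydrogen bond and the O1-H bond lengths with and without that bond.",
  "intramolecular_hbond": {
    "label": "O1-H...O=C",
    "distance_angstrom": 1.739,
    "rho": 0.0425,
    "laplacian": 0.1373,
    "h": -0.0034,
    "ratio": 1.1,
    "be_kcal_printed": -8.7
  },
  "o1h_bond_length_angstrom": {
    "unbound": 0.9669,
    "bound": 0.9843,
    "elongation_percent_printed": 1.8
  },
  "catechol_dihedrals_deg": {
    "C2p-C3p-O3-H": -1.35,
    "C3p-C4p-O4-H": -1.88
  },
  "conformer_gap_kcal": 5.39,
  "solvent_dielectrics": {
    "water": 78.3553,
    "DMSO": 46.826,
    "methanol": 32.613,
    "acetone": 20.493,
    "THF": 7.4257,
    "DCM": 8.93,
    "diethyl_ether": 4.24,
    "benzene": 2.2706
  }
}
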