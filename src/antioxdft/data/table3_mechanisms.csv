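# Free-radical scavenging thermodynamic descriptors (kcal/mol) for luteolin
# and six reference phenolic antioxidants at M06-2X/6-311++G(d,p).
# bde_water is tabulated only for luteolin (explicit-water complexes).
# ip_plus_pde and pa_plus_ete are the tabulated summed columns; note they
# differ by a constant ~0.071 kcal/mol on luteolin rows although the sums are
# algebraically identical -- kept as printed, unreconciled.
compound,site,bde_no_water,bde_water,ip_plus_pde,pa_plus_ete
luteolin,O1-H,88.072,88.681,91.133,91.061
luteolin,O2-H,92.153,93.544,95.213,95.142
luteolin,O3-H,80.662,82.757,83.722,83.651
luteolin,O4-H,83.605,82.096,86.665,86.594
BHA,O1-H,77.161,,80.213,80.150
BHT,O1-H,76.690,,85.515,79.679
GA,O1-H,84.056,,87.118,87.045
GA,O2-H,81.193,,84.255,84.182
PG,O1-H,82.836,,85.897,85.825
PG,O2-H,78.963,,82.025,81.952
PY,O1-H,81.331,,84.388,84.320
PY,O2-H,78.040,,81.098,81.029
TBHQ,O1-H,77.459,,91.776,80.447
TBHQ,O2-H,78.548,,92.866,81.537
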