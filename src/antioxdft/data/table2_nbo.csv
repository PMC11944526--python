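# Second-order perturbation (donor -> acceptor) stabilization energies for
# luteolin-solvent orbital interactions at M06-2X/6-311++G(d,p).
# E(2) values are reference data: the underlying Fock elements are not
# tabulated, so these rows are not recomputable from first principles here.
block,interaction,hyperconjugation,e2_kcal,donor_occupancy,donor_hybrid,acceptor_occupancy,acceptor_hybrid
water,O1...H-Ow,n1(O1) -> sigma*(Ow-H),5.09,1.96714,O1: sp1.52,0.01157,Ow: sp2.85 H: s
water,O2...H-Ow,n1(O2) -> sigma*(Ow-H),5.87,1.96837,O2: sp1.57,0.01279,Ow: sp2.82 H: s
water,O2-H...Ow,n2(Ow) -> sigma*(O2-H),13.81,1.97236,Ow: sp1.06,0.02861,O2: sp2.97 H: s
water,O3...H-Ow,n2(O3) -> sigma*(Ow-H),2.56,1.87545,O3: p,0.01088,Ow: sp2.86 H: s
water,O3-H...Ow,n2(Ow) -> sigma*(O3-H),21.00,1.95287,Ow: sp4.56,0.04652,O3: sp2.83 H: s
water,O4...H-Ow,n2(O4) -> sigma*(Ow-H),3.46,1.97141,O4: sp1.63,0.00902,Ow: sp2.87 H: s
water,O4-H...Ow,n2(Ow) -> sigma*(O4-H),13.46,1.97099,Ow: sp1.69,0.02908,O4: sp3.10 H: s
dmso,O1-H...Od,n1(Od) -> sigma*(O1-H),4.49,1.98584,Od: sp0.30,0.04233,O1: sp2.66 H: s
dmso,O2-H...Od,n2(Od) -> sigma*(O2-H),20.57,1.89740,Od: p,0.05544,O2: sp2.89 H: s
dmso,O3-H...Od,n3(Od) -> sigma*(O3-H),12.72,1.86769,Od: p,0.03811,O3: sp2.86 H: s
dmso,O4-H...Od,n2(Od) -> sigma*(O4-H),14.74,1.91064,Od: p,0.04176,O4: sp2.90 H: s
methanol,O1...H-Om,n1(O1) -> sigma*(Om-H),3.59,1.96886,O1: sp1.52,0.01371,Om: sp2.85 H: s
methanol,O2...H-Om,n1(O2) -> sigma*(Om-H),4.43,1.96914,O2: sp2.19,0.01613,Om: sp3.39 H: s
methanol,O2-H...Om,n2(Om) -> sigma*(O2-H),13.70,1.95560,Om: sp2.84,0.03314,O2: sp2.96 H: s
methanol,O3...H-Om,n2(O3) -> sigma*(Om-H),2.07,1.87565,O3: p,0.01572,Om: sp3.35 H: s
methanol,O3-H...Om,n2(Om) -> sigma*(O3-H),18.63,1.93513,Om: sp6.17,0.04631,O3: sp2.83 H: s
methanol,O4...H-Om,n2(O4) -> sigma*(Om-H),3.22,1.97194,O4: sp1.56,0.01320,Om: sp3.42 H: s
methanol,O4-H...Om,n2(Om) -> sigma*(O4-H),13.40,1.95535,Om: sp3.15,0.03252,O4: sp2.97 H: s
radical_water,[O1*]...H-Ow,n2(O1*) -> sigma*(Ow-H),0.31,0.95732,O1*: p,0.00906,Ow: sp2.72 H: s
radical_water,[O2*]...H-Ow,n1(O2*) -> sigma*(Ow-H),1.18,0.98396,O2*: sp0.69,0.01036,Ow: sp2.67 H: s
radical_water,[O2*]...H-Ow,n2(O2*) -> sigma*(Ow-H),3.35,0.95440,O2*: p,0.01071,Ow: sp2.66 H: s
radical_water,[O3*]...H-Ow,n3(O3*) -> sigma*(Ow-H),1.64,0.88284,O3*: p,0.00857,Ow: sp2.76 H: s
radical_water,[O4*]...H-Ow,n2(O4*) -> sigma*(Ow-H),5.12,0.95218,O4*: p,0.01359,Ow: sp2.58 H: s
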