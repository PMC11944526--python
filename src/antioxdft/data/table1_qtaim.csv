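# QTAIM geometric and topological reference values for luteolin-solvent
# bond critical points at M06-2X/6-311++G(d,p) (a.u. except where noted).
# printed_label preserves the source row labels verbatim, including the
# duplicated "VI" in the water block (row_id disambiguates).
# be_kcal is the tabulated binding energy column.
block,row_id,printed_label,interaction,length_angstrom,angle_deg,rho,laplacian,G,v,h,ratio,be_kcal
water,LW1,I,O1...H-Ow,1.92185,176.9067,0.0222,0.0952,0.0208,-0.0177,0.0030,0.9,-8.43
water,LW2,II,O2-H...Ow,1.63838,171.2233,0.0308,0.1254,0.0296,-0.0279,0.0017,0.9,-11.29
water,LW3,III,O2...H-Ow,1.88308,165.6301,0.0230,0.0977,0.0215,-0.0186,0.0029,0.9,-8.71
water,LW4,VI,O3-H...Ow,1.76759,163.1268,0.0389,0.1314,0.0346,-0.0363,-0.0017,1.0,-14.00
water,LW5,V,O3...H-Ow,2.15803,129.3470,0.0207,0.0852,0.0188,-0.0162,0.0026,0.9,-7.95
water,LW6,VI,O4-H...Ow,1.68388,170.2508,0.0308,0.1210,0.0289,-0.0275,0.0014,1.0,-11.31
water,LW7,VII,O4...H-Ow,1.97618,156.8234,0.0227,0.0969,0.0216,-0.0190,0.0026,0.9,-8.61
dmso,LD1,I,O1...H-Od,1.81451,140.9443,0.0313,0.1232,0.0298,-0.0287,0.0011,1.0,-11.45
dmso,LD2,II,O2...H-Od,1.67271,161.1780,0.0478,0.1499,0.0429,-0.0484,-0.0055,1.1,-16.94
dmso,LD3,III,O3...H-Od,1.74762,167.7532,0.0385,0.1403,0.0363,-0.0375,-0.0012,1.0,-13.85
dmso,LD4,IV,O4...H-Od,1.75890,155.9998,0.0396,0.1374,0.0363,-0.0383,-0.0020,1.1,-14.22
methanol,LM1,I,O1...H-Om,2.02554,143.9005,0.0206,0.0838,0.0187,-0.0164,0.0023,0.9,-7.92
methanol,LM2,II,O2-H...Om,1.76984,160.7465,0.0352,0.1358,0.0336,-0.0333,0.0003,1.0,-12.76
methanol,LM3,III,O2...H-Om,1.98083,149.8292,0.0228,0.0920,0.0208,-0.0186,0.0022,0.9,-8.63
methanol,LM4,IV,O3-H...Om,1.74293,150.5949,0.0393,0.1349,0.0355,-0.0372,-0.0018,1.0,-14.13
methanol,LM5,V,O3...H-Om,1.99651,142.3781,0.0210,0.0868,0.0191,-0.0166,0.0026,0.9,-8.03
methanol,LM6,VI,O4-H...Om,1.77792,163.0294,0.0345,0.1335,0.0329,-0.0324,0.0005,1.0,-12.54
methanol,LM7,VII,O4...H-Om,2.01683,133.3419,0.0221,0.0904,0.0204,-0.0183,0.0021,0.9,-8.42
radical_water,RW1,I,O1...H-Ow,1.89589,150.9920,0.0249,0.1082,0.0241,-0.0211,0.0029,0.9,-9.34
radical_water,RW2,II,O1...H-Ow,2.33842,121.6820,0.0121,0.0457,0.0102,-0.0090,0.0012,0.9,-5.08
radical_water,RW3,III,O2...H-Ow,1.77020,174.8430,0.0240,0.0970,0.0218,-0.0193,0.0025,0.9,-9.04
radical_water,RW4,IV,O2...H-Ow,1.66756,172.9600,0.0275,0.1112,0.0255,-0.0233,0.0023,0.9,-10.22
radical_water,RW5,V,O3...H-Ow,1.96877,155.1870,0.0217,0.0871,0.0193,-0.0168,0.0025,0.9,-8.28
radical_water,RW6,VI,O4...H-Ow,2.23303,118.3900,0.0152,0.0598,0.0133,-0.0116,0.0016,0.9,-6.10
radical_water,RW7,VII,O4...H-Ow,1.82504,177.9680,0.0312,0.1184,0.0284,-0.0272,0.0012,1.0,-11.43
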