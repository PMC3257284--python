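population,environment,clone,frequency,genotype,regulatory_class
G1,Glu,G1-1,0.668,wt,bimodal
G1,Glu,G1-2,0.332,wt,bimodal
G2,Glu,G2-1,1.000,wt,bimodal
G3,Glu,G3-1,1.000,wt,bimodal
G4,Glu,G4-1,1.000,wt,bimodal
G5,Glu,G5-1,1.000,wt,bimodal
G6,Glu,G6-1,1.000,wt,bimodal
L1,Lac,L1-1,1.000,wt,bimodal
L2,Lac,L2-1,1.000,wt,bimodal
L3,Lac,L3-1,0.290,lacI-(ΔTGGC),constitutive
L3,Lac,L3-2,0.697,lacI-(ΔTGGC),constitutive
L3,Lac,L3-3,0.012,lacI-(ΔTGGC),constitutive
L3,Lac,L3-4,0.001,lacI-(ΔTGGC),constitutive
L4,Lac,L4-1,0.999,lacI-(ΩTGGC),constitutive
L4,Lac,L4-2,0.001,lacI-(ΩTGGC),constitutive
L5,Lac,L5-1,1.000,wt,bimodal
L6,Lac,L6-1,0.405,lacI-(ΩTGGC),constitutive
L6,Lac,L6-2,0.595,lacI-(ΩTGGC),constitutive
G+L1,G+L,G+L1-1,0.494,lacI-(ΩTGGC),constitutive
G+L1,G+L,G+L1-2,0.506,lacI-(ΩTGGC),constitutive
G+L2,G+L,G+L2-1,1.000,lacO1-G9T,lower threshold
G+L3,G+L,G+L3-1,1.000,lacO1-G11A,lower threshold
G+L4,G+L,G+L4-1,0.066,lacO1-G5A,lower threshold
G+L4,G+L,G+L4-2,0.934,lacI-(ΩTGGC),constitutive
G+L5,G+L,G+L5-1,0.127,lacO1-G11A,lower threshold
G+L5,G+L,G+L5-2,0.015,lacO1-G11A,lower threshold
G+L5,G+L,G+L5-3,0.858,lacO1-G11A,lower threshold
G+L6,G+L,G+L6-1,0.707,lacO1-G5A,lower threshold
G+L6,G+L,G+L6-2,0.275,lacO1-G5A,lower threshold
G/L1,G/L,G/L1-1,0.005,lacI-(ΔTGGC),constitutive
G/L1,G/L,G/L1-2,0.974,lacI-(ΔTGGC),constitutive
G/L1,G/L,G/L1-3,0.021,lacI-(ΔTGGC),constitutive
G/L2,G/L,G/L2-1,0.052,lacI-(ΔTGGC),constitutive
G/L2,G/L,G/L2-2,0.946,lacI-(ΔTGGC),constitutive
G/L2,G/L,G/L2-3,0.002,wt,bimodal
G/L3,G/L,G/L3-1,0.990,lacI-(ΩTGGC),constitutive
G/L3,G/L,G/L3-2,0.009,wt,bimodal
G/L3,G/L,G/L3-3,0.001,lacI-(ΩTGGC),constitutive
G/L4,G/L,G/L4-1,0.300,lacI-(ΩTGGC),constitutive
G/L4,G/L,G/L4-2,0.638,lacI-(ΩTGGC),constitutive
G/L4,G/L,G/L4-3,0.061,lacI-(L71Q),constitutive
G/L5,G/L,G/L5-1,0.461,No Seq,constitutive
G/L5,G/L,G/L5-2,0.536,No Seq,constitutive
G/L5,G/L,G/L5-3,0.003,No Seq,constitutive
G/L6,G/L,G/L6-1,0.996,lacI-(ΔTGGC),constitutive
G/L6,G/L,G/L6-2,0.004,wt,bimodal
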