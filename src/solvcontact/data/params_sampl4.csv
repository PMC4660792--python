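type_code,description,o_max_A3,s_kcal_per_molA3
C.3_1,sp3 carbon with 1 substituent,350.8,1.619
C.3_2,sp3 carbon with 2 substituents,368.3,0.143
C.3_3,sp3 carbon with 3 substituents,382.5,0.095
C.3_4,sp3 carbon with 4 substituents,377.0,0.794
C.2_1,sp2 carbon with 1 substituent,339.5,0.905
C.2_2,sp2 carbon with 2 substituents,354.8,0.873
C.2_3,sp2 carbon with 3 substituents,353.8,-0.540
C.ar_2,Aromatic carbon with 2 substituents,381.1,-0.889
C.ar_3,Aromatic carbon with 3 substituents,353.2,0.524
C.CO_1,Carbonyl carbon with 1 substituent,354.0,-2.619
C.CO_2,Carbonyl carbon with 2 substituents,369.0,-1.746
N.3_1,sp3 nitrogen with 1 substituent,384.9,-10.318
N.3_2,sp3 nitrogen with 2 substituents,364.4,-10.333
N.3_3,sp3 nitrogen with 3 substituents,393.7,-12.302
N.ar,Aromatic nitrogen,352.4,-11.349
N.pl_1,Planar nitrogen with 1 substituent,358.9,-12.460
N.pl_2,Planar nitrogen with 2 substituents,367.5,-11.667
N.pl_3,Planar nitrogen with 3 substituents,408.9,-11.905
N.no2,Nitrogen in nitro group,372.2,-4.921
O.3_1,sp3 oxygen with 1 substituent,366.2,-11.619
O.3_2,sp3 oxygen with 2 substituents,311.4,-5.873
O.pl_1,Planar oxygen with 1 substituent,316.2,-10.619
O.pl_2,Planar oxygen with 2 substituents,346.8,-6.825
O.es_1,sp3 oxygen in carboxylic acids,327.8,-8.413
O.es_2,sp3 oxygen in esters,333.3,-2.603
O.2,sp2 oxygen,347.6,-9.683
O.no2,Oxygen in nitro group,338.9,0.825
O.intra,Oxygen involved in intramolecular hydrogen bond,309.0,-3.810
Cl,Chlorine,408.7,-3.016
H.C,Hydrogen bonded to carbon,182.2,-0.444
H.N3,Hydrogen bonded to sp3 nitrogen,212.7,-2.540
H.Np,Hydrogen bonded to planar nitrogen,223.8,-1.159
H.O3,Hydrogen bonded to sp3 oxygen,204.8,-9.286
H.Op,Hydrogen bonded to planar oxygen,237.3,-10.889
H.Oa,Hydrogen bonded to carboxylic acid group,202.4,-6.190
H.intra,Hydrogen involved in intramolecular hydrogen bond,210.0,-4.222
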