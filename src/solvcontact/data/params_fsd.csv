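type_code,description,o_max_A3,s_kcal_per_molA3
C.3_1,sp3 carbon with 1 substituent,396.8,0.429
C.3_2,sp3 carbon with 2 substituents,372.4,0.524
C.3_3,sp3 carbon with 3 substituents,361.9,-0.429
C.3_4,sp3 carbon with 4 substituents,379.4,1.222
C.2_1,sp2 carbon with 1 substituent,360.3,2.048
C.2_2,sp2 carbon with 2 substituents,365.1,-0.905
C.2_3,sp2 carbon with 3 substituents,391.3,-1.222
C.1_1,sp carbon with 1 substituent,377.0,-0.905
C.1_2,sp carbon with 2 substituents,351.6,0.143
C.ar_2,Aromatic carbon with 2 substituents,392.9,-1.000
C.ar_3,Aromatic carbon with 3 substituents,375.4,-0.048
C.CO_1,Carbonyl carbon with 1 substituent,337.1,-3.968
C.CO_2,Carbonyl carbon with 2 substituents,393.3,-6.444
N.1_1,sp nitrogen with 1 substituent,404.0,-10.079
N.2_2,sp2 nitrogen with 2 substituents,424.4,-11.556
N.3_1,sp3 nitrogen with 1 substituent,351.6,-9.333
N.3_2,sp3 nitrogen with 2 substituents,437.6,-10.238
N.3_3,sp3 nitrogen with 3 substituents,454.6,-14.921
N.ar,Aromatic nitrogen,357.8,-8.222
N.pl_1,Planar nitrogen with 1 substituent,396.8,-10.159
N.pl_2,Planar nitrogen with 2 substituents,330.0,-10.873
N.pl_3,Planar nitrogen with 3 substituents,358.7,-8.444
N.am_1,Amide nitrogen with 1 substituent,398.9,-8.429
N.am_2,Amide nitrogen with 2 substituents,391.1,-9.603
N.am_3,Amide nitrogen with 3 substituents,399.2,-3.635
N.no2,Nitrogen in nitro group,357.9,-4.444
O.3_1,sp3 oxygen with 1 substituent,330.8,-13.556
O.3_2,sp3 oxygen with 2 substituents,304.4,-5.714
O.es_1,sp3 oxygen in carboxylic acids,309.5,-6.508
O.es_2,sp3 oxygen in esters,319.8,1.778
O.2,sp2 oxygen,302.4,-7.619
O.no2,Oxygen in nitro group,342.1,-0.476
O.intra,Oxygen involved in intramolecular hydrogen bond,323.0,-1.270
S.12,Sulfur with 12 valence electrons,410.3,-3.810
S.3_1,sp3 sulfur with 1 substituent,429.4,-0.762
S.3_2,sp3 sulfur with 2 substituents,402.4,-6.857
S.2,sp2 sulfur,428.6,1.556
S.pl,Planar sulfur,409.5,-0.190
F,Fluorine,284.1,-3.714
F.intra,Fluorine involved in intramolecular hydrogen bond,277.9,1.365
Cl,Chlorine,452.4,-0.794
Cl.intra,Chlorine involved in intramolecular hydrogen bond,458.1,-0.317
Br,Bromine,500.8,-1.778
I,Iodine,549.2,-1.556
P.10,Phosphorus with 10 valence electrons,404.4,-4.095
H.C,Hydrogen bonded to carbon,201.6,0.111
H.N3,Hydrogen bonded to sp3 nitrogen,254.4,-5.556
H.Np,Hydrogen bonded to planar nitrogen,207.9,-1.746
H.O3,Hydrogen bonded to sp3 oxygen,236.7,-7.159
H.Oa,Hydrogen bonded to carboxylic acid group,230.2,-3.444
H.S,Hydrogen bonded to sulfur,228.9,-5.397
H.intra,Hydrogen involved in intramolecular hydrogen bond,222.2,-3.190
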