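compound,subset,dg_exp,dg_calc_no_ihb,error_no_ihb,dg_calc_ihb,error_ihb
1,train_sampl4,-8.62,-9.05,0.43,-7.97,0.65
2,train_sampl4,-8.90,-13.46,4.56,-8.86,0.04
3,train_sampl4,-8.95,-12.74,3.79,-9.08,0.13
4,test_sampl4,-6.78,-11.28,4.50,-8.43,1.65
5,test_sampl4,-4.68,-9.41,4.73,-6.25,1.57
6,test_sampl4,-9.53,-17.03,7.50,-10.87,1.34
7,train_fsd,-4.16,-3.41,0.75,-4.01,0.15
8,train_fsd,-4.55,-6.80,2.25,-6.38,1.83
9,train_fsd,-6.23,-7.71,1.48,-6.65,0.42
10,train_fsd,-23.62,-28.50,4.88,-17.32,6.30
11,train_fsd,-4.58,-8.43,3.85,-7.12,2.54
12,train_fsd,-7.37,-8.25,0.88,-7.76,0.39
13,train_fsd,-18.06,-26.12,8.06,-18.40,0.34
14,test_fsd,-11.85,-18.50,6.65,-14.30,2.45
15,test_fsd,-4.68,-9.18,4.50,-6.92,2.24
16,test_fsd,-7.65,-10.14,2.49,-12.90,5.25
17,test_fsd,-4.91,-6.71,1.80,-5.73,0.82
18,test_fsd,-9.53,-18.64,9.11,-13.79,4.26
19,test_fsd,-5.66,-8.36,2.70,-7.95,2.29
20,test_fsd,-9.40,-12.74,3.34,-9.06,0.34
21,test_fsd,-25.47,-23.69,1.78,-24.08,1.39
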