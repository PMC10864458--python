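equation,algorithm,category,target,term,coefficient
4,LR,mixed,time,intercept,-0.0034
4,LR,mixed,time,R_least,-3.948
4,LR,mixed,time,N,0.000002
4,LR,mixed,time,Harmean,-0.0149
5,C4.5,mixed,time,intercept,0.607
5,C4.5,mixed,time,N,0.000001
5,C4.5,mixed,time,R_least,-2.349
5,C4.5,mixed,time,E_C,-0.7297
5,C4.5,mixed,time,Harmean,-0.011
6,SVM,mixed,time,intercept,-0.4845
6,SVM,mixed,time,N,0.000003
6,SVM,mixed,time,R_least,-2.263
6,SVM,mixed,time,Harmean,-0.0206
6,SVM,mixed,time,R_largest,1.047
7,AB,mixed,time,intercept,2.171
7,AB,mixed,time,N,0.000001
7,AB,mixed,time,R_least,-2.358
7,AB,mixed,time,E_C,-1.205
8,kNN,mixed,time,intercept,0.9135
8,kNN,mixed,time,N,0.000005
8,kNN,mixed,time,R_least,-4.344
8,kNN,mixed,time,E_C,-2.054
9,NB,mixed,time,intercept,-0.6855
9,NB,mixed,time,N,0.000002
9,NB,mixed,time,R_binary,-0.5441
9,NB,mixed,time,ME_V,-1.241
9,NB,mixed,time,R_least,-1.228
9,NB,mixed,time,E_C,-0.528
9,NB,mixed,time,P,0.0013
10,RF,mixed,time,intercept,1.395
10,RF,mixed,time,N,0.000002
10,RF,mixed,time,R_least,-3.898
10,RF,mixed,time,E_C,-1.439
10,RF,mixed,time,Harmean,-0.0167
11,BP,mixed,time,intercept,-4.285
11,BP,mixed,time,N,0.000003
11,BP,mixed,time,R_largest,-4.976
11,BP,mixed,time,E_C,3.845
11,BP,mixed,time,Harmean,-0.008
12,LR,discrete,time,intercept,-1.419
12,LR,discrete,time,N,0.00007
12,LR,discrete,time,N_class,0.0526
12,LR,discrete,time,ENV,0.0074
13,C4.5,discrete,time,intercept,-0.8812
13,C4.5,discrete,time,N,0.00003
13,C4.5,discrete,time,P,0.0015
13,C4.5,discrete,time,N_class,0.0097
14,SVM,discrete,time,intercept,-1.359
14,SVM,discrete,time,N,0.00009
14,SVM,discrete,time,ENV,0.0087
14,SVM,discrete,time,E_C,0.8517
15,AB,discrete,time,intercept,0.8643
15,AB,discrete,time,N,0.00004
15,AB,discrete,time,ENV,0.003
15,AB,discrete,time,N_class,0.0183
15,AB,discrete,time,E_C,-0.4194
15,AB,discrete,time,P,0.0019
16,kNN,discrete,time,intercept,-1.064
16,kNN,discrete,time,N,0.00006
17,NB,discrete,time,intercept,-1.983
17,NB,discrete,time,P,0.0017
17,NB,discrete,time,R_binary,0.1835
17,NB,discrete,time,N,0.000018
18,RF,discrete,time,intercept,-1.641
18,RF,discrete,time,N,0.00005
18,RF,discrete,time,E_C,1.566
19,BP,discrete,time,intercept,-0.7675
19,BP,discrete,time,N,0.00006
19,BP,discrete,time,N_class,0.0549
20,LR,continuous,time,intercept,-0.5703
20,LR,continuous,time,N,0.000009
20,LR,continuous,time,R_least,-1.897
20,LR,continuous,time,N_class,0.0322
20,LR,continuous,time,Geomean,0.0000008
21,C4.5,continuous,time,intercept,-0.2581
21,C4.5,continuous,time,N,0.000006
21,C4.5,continuous,time,R_least,-0.7944
22,SVM,continuous,time,intercept,0.0992
22,SVM,continuous,time,N,0.00001
22,SVM,continuous,time,Geomean,0.000001
22,SVM,continuous,time,MAr,-4.144
22,SVM,continuous,time,R_least,-1.998
23,AB,continuous,time,intercept,1.221
23,AB,continuous,time,N,0.000008
23,AB,continuous,time,Geomean,0.0000003
23,AB,continuous,time,R_least,-0.5567
24,kNN,continuous,time,intercept,-0.3235
24,kNN,continuous,time,N,0.00001
24,kNN,continuous,time,Geomean,0.0000008
24,kNN,continuous,time,MAr,-3.446
24,kNN,continuous,time,R_least,-1.569
25,NB,continuous,time,intercept,-1.578
25,NB,continuous,time,N,0.000004
26,RF,continuous,time,intercept,0.1164
26,RF,continuous,time,N,0.000009
26,RF,continuous,time,R_least,-1.513
26,RF,continuous,time,Geomean,0.0000006
27,BP,continuous,time,intercept,0.7947
27,BP,continuous,time,N,0.00001
27,BP,continuous,time,R_least,-2.448
27,BP,continuous,time,MAr,-3.449
28,LR,mixed,memory,intercept,5.055
28,LR,mixed,memory,N,0.000003
28,LR,mixed,memory,R_least,-1.556
28,LR,mixed,memory,R_largest,0.7283
28,LR,mixed,memory,R_binary,0.554
29,C4.5,mixed,memory,intercept,3.354
29,C4.5,mixed,memory,P,0.0021
29,C4.5,mixed,memory,N,0.000002
29,C4.5,mixed,memory,R_largest,1.574
29,C4.5,mixed,memory,E_C,0.9187
30,SVM,mixed,memory,intercept,6.427
30,SVM,mixed,memory,N,0.000002
30,SVM,mixed,memory,R_least,-2.149
30,SVM,mixed,memory,Harmean,-0.011
30,SVM,mixed,memory,Skewness,-0.1251
31,AB,mixed,memory,intercept,6.535
31,AB,mixed,memory,N,0.000002
31,AB,mixed,memory,R_binary,2.05
31,AB,mixed,memory,R_largest,0.5903
31,AB,mixed,memory,R_discrete,-1.148
31,AB,mixed,memory,E_C,1.454
32,kNN,mixed,memory,intercept,5.206
32,kNN,mixed,memory,N,0.000003
32,kNN,mixed,memory,R_least,-1.84
32,kNN,mixed,memory,R_largest,1.174
33,NB,mixed,memory,intercept,4.559
33,NB,mixed,memory,P,0.0018
33,NB,mixed,memory,N,-0.0000005
34,RF,mixed,memory,intercept,6.851
34,RF,mixed,memory,N,0.000002
34,RF,mixed,memory,R_least,-1.088
34,RF,mixed,memory,Harmean,-0.008
35,BP,mixed,memory,intercept,2.306
35,BP,mixed,memory,N,0.000003
35,BP,mixed,memory,R_largest,3.272
35,BP,mixed,memory,MAr,0.7722
35,BP,mixed,memory,E_C,2.417
35,BP,mixed,memory,Harmean,-6.748
36,LR,discrete,memory,intercept,4.872
36,LR,discrete,memory,N,0.00004
36,LR,discrete,memory,N_class,0.0346
37,C4.5,discrete,memory,intercept,4.5535
37,C4.5,discrete,memory,P,0.0027
38,SVM,discrete,memory,intercept,5.668
38,SVM,discrete,memory,N,0.00004
38,SVM,discrete,memory,N_class,0.0246
38,SVM,discrete,memory,R_largest,-1.206
39,AB,discrete,memory,intercept,7.115
39,AB,discrete,memory,N,0.00004
39,AB,discrete,memory,P,0.0021
39,AB,discrete,memory,ENV,0.0041
40,kNN,discrete,memory,intercept,4.891
40,kNN,discrete,memory,N,0.00004
40,kNN,discrete,memory,N_class,0.0152
40,kNN,discrete,memory,P,0.0019
41,NB,discrete,memory,intercept,5.1462
41,NB,discrete,memory,P,0.0018
41,NB,discrete,memory,ME_V,-1.6206
41,NB,discrete,memory,R_binary,-0.3956
41,NB,discrete,memory,N_class,0.0119
41,NB,discrete,memory,NSR,0.0026
42,RF,discrete,memory,intercept,5.872
42,RF,discrete,memory,N,0.00004
42,RF,discrete,memory,E_C,0.6054
43,BP,discrete,memory,intercept,4.715
43,BP,discrete,memory,N,0.00004
43,BP,discrete,memory,N_class,0.0407
44,LR,continuous,memory,intercept,5.913
44,LR,continuous,memory,N,0.000008
44,LR,continuous,memory,R_least,-1.76
44,LR,continuous,memory,Geomean,0.0000006
44,LR,continuous,memory,MAr,-2.448
45,C4.5,continuous,memory,intercept,4.626
45,C4.5,continuous,memory,N,0.000004
45,C4.5,continuous,memory,Geomean,0.0000004
45,C4.5,continuous,memory,P,0.0036
45,C4.5,continuous,memory,Skewness,-0.0754
46,SVM,continuous,memory,intercept,5.996
46,SVM,continuous,memory,N,0.000008
46,SVM,continuous,memory,R_least,-1.687
47,AB,continuous,memory,intercept,7.588
47,AB,continuous,memory,N,0.000006
47,AB,continuous,memory,Geomean,0.0000005
47,AB,continuous,memory,MAr,-1.6
47,AB,continuous,memory,R_least,-0.7407
48,kNN,continuous,memory,intercept,5.916
48,kNN,continuous,memory,N,0.000008
48,kNN,continuous,memory,Geomean,0.0000007
48,kNN,continuous,memory,R_least,-1.515
48,kNN,continuous,memory,MAr,-2.27
49,NB,continuous,memory,intercept,4.0255
49,NB,continuous,memory,P,0.0053
49,NB,continuous,memory,N_class,0.0088
49,NB,continuous,memory,E_C,0.2934
50,RF,continuous,memory,intercept,6.806
50,RF,continuous,memory,N,0.000005
50,RF,continuous,memory,Geomean,0.0000008
50,RF,continuous,memory,R_least,-1.186
50,RF,continuous,memory,MAr,-1.637
51,BP,continuous,memory,intercept,5.83
51,BP,continuous,memory,N,0.000008
51,BP,continuous,memory,R_least,-1.986
51,BP,continuous,memory,Geomean,0.0000006
51,BP,continuous,memory,MAr,-2.158
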