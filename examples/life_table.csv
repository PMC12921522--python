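age,sex,qx
0,female,0.00019998000133325533
1,female,0.00020192884433134495
2,female,0.00020406762057756378
3,female,0.0002064148404021804
4,female,0.00020899081800163088
5,female,0.0002118178472091392
6,female,0.00021492039438852917
7,female,0.00021832531011867218
8,female,0.00022206206149799623
9,female,0.00022616298707667237
10,female,0.0002306635766179399
11,female,0.00023560277810774632
12,female,0.000241023334661139
13,female,0.0002469721542368575
14,female,0.0002535007153512403
15,female,0.0002606655122930901
16,female,0.000268528543679869
17,female,0.0002771578485719628
18,female,0.0002866280947652067
19,female,0.0002970212243343928
20,female,0.00030842716198919984
21,female,0.00032094459234355277
22,female,0.00033468181278917264
23,female,0.00034975766931177876
24,female,0.00036630258329661824
25,female,0.000384459678146043
26,female,0.000404386015385394
27,female,0.0004262539508624874
28,female,0.000450252622667513
29,female,0.0004765895835193712
30,female,0.0005054925915843889
31,female,0.0005372115750339468
32,female,0.0005720207871113825
33,female,0.0006102211700782512
34,female,0.0006521429481635144
35,female,0.0006981484715479214
36,female,0.0007486353355090625
37,female,0.0008040398011324168
38,female,0.0008648405464818376
39,female,0.0009315627798407444
40,female,0.0010047827495912598
41,female,0.0010851326885223944
42,female,0.0011733062338650235
43,female,0.0012700643681627932
44,female,0.0013762419302308926
45,female,0.0014927547499433702
46,female,0.0016206074654623315
47,female,0.001760902086784033
48,female,0.0019148473751712247
49,female,0.002083769114173184
50,female,0.002269121354539716
51,female,0.0024724987224270523
52,female,0.0026956498878800694
53,female,0.002940492298688535
54,female,0.0032091282933327525
55,female,0.003503862715875883
56,female,0.003827222165297184
57,female,0.004181976021865874
58,female,0.004571159403687686
59,female,0.004998098217434799
60,female,0.005466436478405168
61,female,0.005980166086307914
62,female,0.00654365925436351
63,female,0.0071617038002070865
64,female,0.007839541517388082
65,female,0.008582909855605725
66,female,0.009398087145715217
67,female,0.010291941611408228
68,female,0.011271984412577152
69,female,0.01234642696482069
70,female,0.013524242774235806
71,female,0.014815234015251866
72,female,0.016230103060166923
73,female,0.01778052914031958
74,female,0.01947925027815145
75,female,0.02134015057401395
76,female,0.023378352858187124
77,female,0.025610316623330465
78,female,0.028053941030966922
79,female,0.030728672632328924
80,female,0.033655617252873804
81,female,0.036857655254014965
82,female,0.040359559097139064
83,female,0.044188111784853046
84,female,0.04837222433264654
85,female,0.052943049919905394
86,female,0.05793409177075903
87,female,0.06338130111040485
88,female,0.06932316071899591
89,female,0.07580074865114073
90,female,0.08285777559424468
91,female,0.09054058809579302
92,female,0.09889812849524782
93,female,0.10798184085443185
94,female,0.11784551050499292
95,female,0.1285450230505658
96,female,0.14013802682118948
97,female,0.15268348094974826
98,female,0.16624106952801776
99,female,0.18087046084671132
100,female,0.19663038972245928
0,male,0.0003319448940986014
1,male,0.0003350626295037795
2,male,0.0003384842136204824
3,male,0.00034223925778376074
4,male,0.0003463602588329451
5,male,0.00035088288024265335
6,male,0.00035584626063334124
7,male,0.000361293352326153
8,male,0.00036727129286595606
9,male,0.00037383181271943844
10,male,0.00038103168266689913
11,male,0.00038893320474808757
12,male,0.0003976047509972602
13,male,0.00040712135461185017
14,male,0.00041756535865122846
15,male,0.00042902712785464203
16,male,0.0004416058297092018
17,male,0.00045541029148943313
18,male,0.0004705599406451544
19,male,0.00048718583662132886
20,male,0.0005054318029762417
21,male,0.0005254556695210022
22,male,0.0005474306351367364
23,male,0.0005715467629532345
24,male,0.00059801262069481
25,male,0.0006270570802292541
26,male,0.0006589312916974732
27,male,0.000693910849075996
28,male,0.00073229816563114
29,male,0.0007744250794824437
30,male,0.0008206557114148749
31,male,0.0008713895991798726
32,male,0.000927065134813998
33,male,0.0009881633340079743
34,male,0.0010552119692839312
35,male,0.001128790101712518
36,male,0.001209533049135847
37,male,0.0012981378323876358
38,male,0.0013953691448276295
39,male,0.0015020658946688359
40,male,0.0016191483740842783
41,male,0.0017476261139725002
42,male,0.0018886064885443865
43,male,0.002043304139609625
44,male,0.002213051296599877
45,male,0.0023993090749947488
46,male,0.002603679842928308
47,male,0.0028279207533796757
48,male,0.003073958547475608
49,male,0.003343905743091735
50,male,0.0036400783320965635
51,male,0.003965015119250848
52,male,0.004321498845901162
53,male,0.004712579252157623
54,male,0.005141598242140555
55,male,0.005612217328025415
56,male,0.006128447539865078
57,male,0.006694681999351193
58,male,0.007315731366548617
59,male,0.007996862378904734
60,male,0.00874383971110726
61,male,0.009562971392174546
62,male,0.010461158021894512
63,male,0.011445946031667265
64,male,0.012525585234022474
65,male,0.013709090899486243
66,male,0.015006310587709182
67,male,0.01642799594020805
68,male,0.01798587961277409
69,male,0.019692757484205292
70,male,0.02156257622174862
71,male,0.023610526209189575
72,male,0.025853139746989107
73,male,0.02830839431070853
74,male,0.030995820498832427
75,male,0.033936614107891616
76,male,0.03715375153441869
77,male,0.04067210741176053
78,male,0.044518573036084086
79,male,0.04872217371006193
80,male,0.05331418262376164
81,male,0.05832822828848028
82,male,0.06380039182842856
83,male,0.06976928960498852
84,male,0.0762761356870123
85,male,0.0833647775781251
86,male,0.0910816973608981
87,male,0.09947596901540001
88,male,0.10859916112037704
89,male,0.11850517246369419
90,male,0.1292499863033555
91,male,0.14089132717916686
92,male,0.1534882023508094
93,male,0.16710030823598598
94,male,0.1817872807882135
95,male,0.19760776778334443
96,male,0.21461830073186472
97,male,0.23287194492369168
98,male,0.2524167083424762
99,male,0.273293694335319
100,male,0.29553498954517887
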