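# Two-term Ogden constants identified per porcine levator ani specimen
# (20 specimens, 10 animals, left/right).  Units: mu in MPa, alpha
# dimensionless.  The published mu1 and alpha2 summary statistics are
# internally inconsistent with these columns; alpha1 and mu2 recompute
# cleanly (population SD).
specimen,mu1_mpa,alpha1,mu2_mpa,alpha2
1,0.0074,0.0800,0.0000,5.9561
2,0.0043,0.0400,0.0000,6.3397
3,0.0016,0.2234,0.0011,19.300
4,0.0295,0.5006,0.0057,11.678
5,0.0019,0.0135,0.0022,9.0668
6,0.0001,0.0010,0.0136,10.156
7,0.0059,0.2094,0.0352,20.608
8,0.0046,0.2464,0.0229,13.405
9,0.0029,0.2267,0.0584,14.055
10,0.0027,0.2784,0.0516,14.167
11,0.0025,0.1328,0.0509,11.057
12,0.0019,0.1531,0.0228,15.995
13,0.0062,0.0932,0.0081,19.444
14,0.0010,0.0400,0.0212,20.034
15,0.0096,0.2571,0.0192,14.736
16,0.0029,0.1698,0.0108,15.058
17,0.0082,0.0803,0.0342,16.270
18,0.0270,0.1480,0.0333,16.947
19,0.0262,0.2640,0.0156,12.308
20,0.0172,0.4486,0.0248,15.667
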