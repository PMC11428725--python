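run,dpph,frap,tpc
1,80.03,124.03,107.60
2,90.91,154.68,100.55
3,50.56,173.86,70.00
4,93.88,144.68,130.31
5,119.72,207.41,123.91
6,117.40,217.71,137.75
7,236.11,274.15,158.90
8,319.80,429.46,158.94
9,205.53,313.00,180.55
10,121.93,186.74,110.35
11,165.07,249.51,111.00
12,116.96,202.20,131.99
13,141.92,225.96,120.49
14,168.19,255.13,131.82
15,218.12,273.73,146.86
16,311.50,364.13,155.19
17,326.93,393.38,165.17
18,341.79,485.69,233.86
19,314.86,494.92,241.04
20,231.34,344.60,233.94
21,212.08,315.31,249.10
22,258.35,381.11,338.50
23,249.25,341.47,364.56
24,315.08,445.88,358.56
25,368.56,489.75,282.63
26,337.29,435.94,290.92
27,359.10,526.07,340.89
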