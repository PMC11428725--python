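run,temperature,ethanol,time,yield_pct,yield_pct_sd,dpph,dpph_sd,frap,frap_sd,tpc,tpc_sd,tfc,tfc_sd,ctc,ctc_sd,htc,htc_sd
1,20,0,3,0.61,0.03,72.69,3.57,134.32,9.15,104.45,1.16,177.21,10.91,13.09,1.26,161.82,7.55
2,20,0,6,0.63,0.01,92.66,3.55,145.65,7.79,105.18,17.61,234.19,20.83,5.34,0.46,187.64,9.32
3,20,0,24,0.78,0.05,41.88,7.46,135.10,4.13,114.46,13.45,299.03,37.81,5.70,0.54,202.88,13.96
4,20,20,3,0.67,0.02,120.78,2.96,215.87,8.01,103.87,1.39,225.38,10.75,5.55,0.63,182.83,17.77
5,20,20,6,0.92,0.08,116.87,5.94,196.71,11.69,107.29,45.76,251.13,10.17,7.71,0.88,191.70,15.54
6,20,20,24,1.03,0.08,112.53,6.47,199.78,19.26,121.82,3.01,301.84,23.50,5.60,0.46,71.75,0.96
7,20,40,3,0.76,0.02,220.89,8.12,252.48,15.78,150.76,1.04,277.22,17.31,19.51,1.71,301.72,3.85
8,20,40,6,1.09,0.03,308.96,14.91,474.09,44.52,167.19,8.83,280.49,28.01,36.95,2.43,284.59,26.30
9,20,40,24,1.46,0.09,165.69,8.43,303.11,26.73,169.16,26.57,324.47,12.30,36.57,3.43,118.97,10.74
10,50,0,3,0.87,0.07,104.49,6.85,190.43,6.28,98.82,9.49,276.22,23.26,38.75,3.64,217.85,10.30
11,50,0,6,1.03,0.04,195.99,15.98,241.46,13.35,122.95,4.07,278.36,25.93,8.74,0.77,371.73,32.03
12,50,0,24,1.12,0.08,165.69,8.43,214.05,16.02,131.17,0.12,323.66,25.68,8.97,0.16,152.46,12.57
13,50,20,3,1.30,0.05,112.44,6.05,316.91,17.35,139.18,13.21,301.84,11.23,13.51,4.33,218.73,8.00
14,50,20,6,1.62,0.07,165.69,8.43,250.94,21.47,142.38,0.37,312.25,27.83,14.50,1.33,162.55,14.71
15,50,20,24,1.73,0.08,203.64,5.75,285.25,11.90,143.95,4.09,317.85,31.11,13.60,0.48,217.51,20.11
16,50,40,3,1.44,0.05,322.41,9.75,362.79,3.36,148.16,17.27,297.84,9.02,46.79,3.06,410.08,35.66
17,50,40,6,1.69,0.06,238.77,7.92,287.31,21.35,152.97,9.10,297.04,13.25,26.74,2.55,521.61,45.63
18,50,40,24,2.33,0.14,347.71,25.97,518.48,51.93,175.98,17.70,347.08,24.71,38.18,2.98,261.22,23.77
19,80,0,3,1.39,0.08,299.60,5.66,511.04,26.71,234.04,6.43,263.61,16.89,34.10,1.48,203.48,19.72
20,80,0,6,1.43,0.07,239.29,10.51,327.34,27.20,239.19,14.59,279.16,17.53,16.38,1.48,359.12,26.16
21,80,0,24,1.95,0.05,209.33,2.89,314.25,27.46,246.83,29.19,304.24,4.21,8.95,0.80,276.43,17.66
22,80,20,3,1.83,0.08,326.85,8.95,459.44,42.61,340.69,1.70,263.81,12.79,36.69,2.39,530.85,50.88
23,80,20,6,1.92,0.10,242.53,12.83,347.02,26.92,361.30,36.53,274.62,6.79,27.17,2.53,378.71,3.62
24,80,20,24,2.67,0.12,324.98,2.87,439.91,36.33,365.79,14.77,329.46,28.33,74.82,6.57,436.89,12.34
25,80,40,3,2.28,0.16,359.87,9.72,496.85,44.57,285.46,21.20,394.45,36.83,40.87,2.83,863.07,25.67
26,80,40,6,2.46,0.10,341.56,7.11,427.55,36.92,290.76,11.12,427.01,12.12,74.82,6.57,821.22,46.95
27,80,40,24,2.85,0.19,365.78,1.95,519.11,41.19,329.59,32.78,433.75,15.57,44.67,4.01,591.50,42.93
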