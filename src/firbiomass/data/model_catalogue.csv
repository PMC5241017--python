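id,formula,response_scale,a,b,c,d,e,mab,rmse,r2,status,note
1,ln(B) = a + b*ln(D) + c*ln(H)^2 + d*ln(H)^3 + e*ln(WD),log,-5.744,2.480,-0.217,-0.278,0.60,7.675,13.656,0.982,converged,reference values suspect: printed coefficients predict ~0.06 kg at the sample-mean tree; digits likely truncated or columns shifted
2,B = exp(a) * (D+1)^b * H^c * exp(d*D) * exp(e*H),natural,-6.104,5.162,-1.340,-0.138,0.10,8.017,11.750,0.987,converged,errata: source prints '(D + 1^b'; repaired to '(D+1)^b' by parallel with form 3
3,B = exp(a) * (D+1)^b * H^c * exp(d*D),natural,-6.250,3.389,0.704,-0.064,,8.601,12.602,0.985,converged,
4,B = a + b*D + c*D^2 + d*H + e*D*H,natural,-2.878,4.827,-0.124,-7.493,0.60,9.892,13.796,0.981,converged,reference values suspect: printed coefficient signs/magnitudes look inconsistent with the form; row stored verbatim
5,ln(B) = a + b*ln(D^2*H) + c*ln(WD),log,-4.720,0.831,0.370,,,10.007,18.936,0.967,converged,
6,ln(B) = a + b*ln(D) + c*ln(WD),log,-5.702,2.546,0.504,,,10.025,19.425,0.965,converged,
7,ln(B) = a + b*ln(D) + c*ln(H) + d*ln(WD),log,-5.723,2.567,-0.020,0.507,,10.095,19.895,0.965,converged,
8,B = a + b*D + c*D^2 + d*(D^3/H),natural,-9.452,-0.808,0.572,-0.171,,10.961,14.627,0.979,converged,
9,B = a + b*D^2 + c*D + d*D*H,natural,-10.924,-0.696,0.198,0.200,,11.029,14.847,0.979,converged,reference values suspect: printed column order inconsistent with the form (prediction negative at the sample-mean tree; plausible if b and c are swapped)
10,B = a + b*D^2 + c*D*H,natural,-16.477,0.195,0.183,,,11.130,14.894,0.978,converged,
11,ln(B) = a + b*(D/(D+10)),log,-2.411,10.864,,,,11.440,15.666,0.976,converged,
12,ln(B) = a + b*(D/(D+7)) + c*H + d*ln(H),log,-2.785,10.899,0.005,-0.046,,11.558,21.683,0.954,converged,
13,ln(B) = a + b*(D/(D+11)) + c*ln(H),log,-2.121,10.451,0.071,,,11.628,16.219,0.974,converged,
14,B = exp(a + b*ln(D^2*H)),natural,-1.823,0.748,,,,11.809,16.116,0.975,converged,
15,B = a*(D^2*H)^b,natural,0.162,0.748,,,,11.809,16.116,0.975,converged,
16,B = a*D^b*H^c,natural,0.171,1.574,0.650,,,11.943,15.834,0.976,converged,
17,ln(B) = a + b*(D/(D+11)),log,-2.111,10.757,,,,11.970,16.732,0.973,converged,
18,B = exp(a) * (D+1)^b * H^c,natural,-2.050,1.617,0.674,,,12.316,16.148,0.975,converged,
19,B = exp(a + b*ln(D^2*H*G)),natural,-1.543,0.436,,,,12.455,16.285,0.975,converged,reference values consistent with basal area G expressed in cm^2; this package uses m^2
20,B = a + b*H + c*D^2,natural,-24.870,1.493,0.319,,,12.669,16.118,0.975,converged,
21,ln(B) = a + b*(D/(D+13)) + c*H + d*ln(H),log,-1.582,10.205,0.005,0.040,,12.796,21.425,0.955,converged,
22,B = a + b*D^2,natural,-11.692,0.349,,,,12.853,16.582,0.973,converged,
23,B = a + b*D^2*H + c*D^2,natural,-13.130,0.001,0.363,,,12.940,16.810,0.973,converged,
24,B = a + b*D + c*D^2*H,natural,-48.700,6.542,0.006,,,12.968,16.736,0.974,converged,
25,B = a + b*D^c,natural,-20.336,0.559,1.869,,,13.007,16.442,0.974,converged,
26,ln(B) = a + b*(D/(D+14)) + c*ln(H),log,-1.499,10.211,0.106,,,13.028,21.937,0.953,converged,
27,ln(B) = a + b*(D/(D+13)),log,-1.643,10.667,,,,13.037,20.706,0.958,converged,
28,B = a + b*D + c*D^2,natural,-23.013,1.314,0.317,,,13.118,16.628,0.974,converged,
29,ln(B) = a + b*(D/(D+14)),log,-1.456,10.666,,,,13.578,23.191,0.948,converged,
30,ln(B) = a + b*(D/(D+18)) + c*H + d*ln(H),log,-1.338,10.419,-0.020,0.360,,13.790,23.329,0.947,converged,
31,B = a*D^b,natural,0.245,2.090,,,,14.713,18.004,0.969,converged,
32,B = exp(a + b*ln(D)),natural,-1.407,2.090,,,,14.713,18.004,0.969,converged,errata: source prints unbalanced 'exp(a + b * ln(D)'; closing parenthesis restored
33,ln(B) = a + b*ln(D) + c*ln(H*D^2),log,-2.821,2.117,0.143,,,14.812,29.533,0.915,converged,
34,ln(B) = a + b*(D/(D+5)),log,-5.560,13.001,,,,14.864,24.769,0.940,converged,
35,ln(B) = a + b*ln(D) + c*H + d*ln(H*D^2),log,-2.794,2.139,0.001,0.130,,14.879,30.159,0.911,converged,
36,ln(B) = a + b*ln(D) + c*H,log,-2.676,2.441,0.008,,,15.654,34.441,0.884,converged,
37,ln(B) = a + b*ln(D),log,-2.843,2.550,,,,15.682,32.304,0.901,converged,
38,ln(B) = a + b*ln(pi*D),log,-5.762,2.550,,,,15.682,31.826,0.901,converged,
39,ln(B) = a + b*(D/(D+30)) + c*H + d*ln(H),log,-1.261,11.587,-0.005,0.074,,15.714,28.420,0.921,converged,
40,ln(B) = a + b*(D/(D+18)),log,-0.901,10.841,,,,15.877,34.020,0.887,converged,
41,B = a*(WD*D^2*H)/1000,natural,0.054,,,,,15.900,35.951,0.878,converged,
42,B = a + b*H + c*D^2*H,natural,-24.710,4.595,0.008,,,15.983,20.399,0.961,converged,
43,B = a + b*D^2*H + c*H^2,natural,1.586,0.007,0.197,,,15.996,20.989,0.958,converged,
44,B = a + b*D + c*(D^2*H)^2,natural,-85.590,10.830,0.000,,,16.618,21.062,0.958,converged,
45,B = a + b*H^2 + c*H^3,natural,0.373,0.155,0.010,,,20.297,27.868,0.924,converged,
46,B = a*H^b,natural,0.061,2.595,,,,20.318,28.225,0.925,converged,
47,B = a + b*D + c*H^2,natural,-81.275,7.637,0.200,,,20.367,26.335,0.934,converged,
48,B = a*V + b,natural,312.470,24.740,,,,20.502,26.497,0.934,converged,
49,B = a + b*D^2*H,natural,27.464,0.011,,,,20.986,27.187,0.930,converged,
50,B = a + b*D,natural,-118.191,13.264,,,,22.249,29.696,0.917,converged,
51,B = a + b*D + c*H,natural,-115.504,15.366,-2.428,,,22.285,29.212,0.919,converged,
52,B = a*H*D^2,natural,0.013,,,,,23.777,34.283,0.886,converged,
53,B = a + b*H + c*(D^2*H)^2,natural,-64.280,9.985,0.000,,,25.411,30.737,0.911,converged,
54,B = a + b*(1/D^2*H)*D^2*H,natural,-23.380,0.445,,,,25.779,31.257,0.905,converged,literal left-to-right reading reduces to a + b*H^2; D cancels
55,ln(B) = a + b*ln(D)^2,log,0.405,0.484,,,,26.178,81.410,0.355,converged,
56,B = a*exp(H*b),natural,14.665,0.112,,,,26.306,32.099,0.900,converged,
57,B = a*exp(b*D),natural,23.845,0.081,,,,28.721,32.615,0.899,converged,
58,B = a*BA^b*SI^c,natural,1.067,0.604,1.206,,,30.605,61.748,0.640,converged,SI (site index) has no default and no documented provenance; skipped when SI absent
59,ln(B) = ln(a) + b*H,log,4.070,0.172,,,,34.697,90.892,0.219,converged,
60,B = a + b*H,natural,-105.634,13.467,,,,36.505,47.096,0.790,converged,
61,B = a + b*ln(D),natural,-387.080,180.950,,,,37.662,53.784,0.727,converged,
62,B = a*ln(H*D^2) + b,natural,58.273,-365.449,,,,38.751,55.563,0.699,converged,errata: printed row has a shifted/empty cell; read as the 2-parameter ln form with a=58.273 b=-365.449 (cf. form 63)
63,B = a + b*ln(D^2*H),natural,-365.451,58.274,,,,38.751,56.399,0.699,converged,
64,B = a + b*ln(H),natural,-295.080,151.940,,,,45.808,64.782,0.603,converged,
65,ln(B) = ln(a) + b*D,log,,,,,,,,,misconverged,
66,ln(B) = ln(a) + b*D^2*H,log,,,,,,,,,misconverged,
67,B = (WD/a)*exp(b*ln(D) + c*ln(D)^2 + d*ln(D)^3 + e),natural,,,,,,,,,misconverged,
68,B = (WD/a)*exp(b*ln(D) + c),natural,,,,,,,,,misconverged,
69,B = exp(a + b*ln(D) + c*ln(D)^2 + d*ln(H) + e*ln(G)),natural,,,,,,,,,misconverged,
70,B = a*H^b*(D+1)^(c + d*ln(D)),natural,,,,,,,,,misconverged,
71,B = a*D^2 + (D^2 - b)*c,natural,,,,,,,,,misconverged,parameters b and c enter only through a*D^2 + c*D^2 - b*c; not jointly identifiable
72,ln(B) = a + b*ln(D) + c*ln(D^2) + d*ln(H),log,,,,,,,,,misconverged,b and c collinear: b*ln(D) + 2*c*ln(D)
73,B = exp(a + b*ln(D)) + exp(c + d*ln(D)),natural,,,,,,,,,misconverged,symmetric in the two exponential terms; label-switching
74,B = a + (b*(1/D^2) + c*(1/D^2))*D^2,natural,,,,,,,,,misconverged,reduces to a + b + c; only the sum is identifiable
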