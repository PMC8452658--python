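ID,Date,Latitude,Longitude,Crop cover,Mean_LAI_U1,Uncertainty,Standard deviation,Mean_LAI_U2,Scaling difference
5,2003/3/30,33.81258,114.63295,0.86,2.451,0.569,0.952,2.349,0.102
11,2003/3/30,33.74116,114.42932,0.88,2.228,0.517,0.980,2.406,-0.178
14,2003/3/30,33.73983,114.69064,0.96,3.202,0.743,1.214,2.855,0.347
16,2003/3/30,33.71973,114.37526,0.93,3.207,0.744,1.181,3.454,-0.247
2,2004/4/8,35.14029,113.02383,0.93,2.561,0.336,1.770,1.758,0.803
6,2004/4/8,35.11618,112.99328,0.96,2.733,0.358,1.721,2.741,-0.008
8,2004/4/8,34.95611,112.76271,0.83,3.604,0.472,2.053,2.820,0.784
11,2004/4/8,34.93798,112.99126,0.79,3.567,0.467,1.981,2.774,0.793
2,2004/4/24,35.14029,113.02383,0.93,3.168,0.215,1.777,2.455,0.712
6,2004/4/24,35.11807,112.99333,0.95,3.436,0.234,1.571,3.608,-0.172
8,2004/4/24,34.95611,112.76271,0.83,3.746,0.255,1.547,3.267,0.479
11,2004/4/24,34.93798,112.99126,0.79,2.641,0.180,0.951,2.339,0.302
2,2004/5/10,35.14029,113.02383,0.93,3.118,0.243,1.401,2.560,0.558
6,2004/5/10,35.11706,112.98935,0.95,4.310,0.336,1.843,4.154,0.155
7,2004/5/10,34.95611,112.76271,0.83,3.607,0.281,1.331,3.287,0.320
10,2004/5/10,34.93798,112.99126,0.79,2.892,0.226,0.960,2.587,0.305
2,2004/5/17,35.14029,113.02383,0.93,2.347,0.305,1.295,1.776,0.570
6,2004/5/17,35.11837,112.99169,0.95,2.448,0.318,1.123,2.411,0.037
8,2004/5/17,34.95611,112.76271,0.83,2.059,0.268,0.902,1.878,0.181
11,2004/5/17,34.93659,112.99319,0.76,1.615,0.210,0.669,1.426,0.189
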