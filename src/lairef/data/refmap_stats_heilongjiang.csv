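ID,Date,Latitude,Longitude,Crop cover,Mean_LAI_U1,Uncertainty,Standard deviation,Mean_LAI_U2,Scaling difference
3,2005/5/23,46.78729,131.88652,1.00,0.763,0.269,0.437,0.835,-0.073
4,2005/5/23,46.78593,131.97661,0.85,0.466,0.165,0.236,0.517,-0.051
14,2005/5/23,46.75035,131.83915,0.92,0.375,0.132,0.190,0.328,0.047
19,2005/5/23,46.70117,131.86714,0.98,0.293,0.103,0.120,0.282,0.011
3,2006/6/2,46.77431,131.74556,0.88,0.702,0.100,0.393,0.689,0.012
4,2006/6/2,46.76551,131.8512,0.98,0.812,0.116,0.456,0.806,0.006
8,2006/6/2,46.74023,131.75914,0.94,0.812,0.116,0.488,0.735,0.077
13,2006/6/2,46.71375,131.715,1.00,0.654,0.093,0.413,0.555,0.098
1,2007/6/14,46.80207,131.80545,0.96,1.135,0.280,0.650,1.206,-0.071
2,2007/6/14,46.79537,131.89549,1.00,1.338,0.331,0.772,1.516,-0.178
3,2007/6/14,46.79412,131.75324,0.84,1.202,0.297,0.762,1.303,-0.101
16,2007/6/14,46.72528,131.89951,0.97,1.312,0.324,0.845,0.957,0.355
8,2005/5/23,46.79189,131.90669,0.91,0.709,0.274,0.355,0.651,0.058
14,2005/5/23,46.7641,131.74208,0.96,0.505,0.195,0.306,0.481,0.024
15,2005/5/23,46.75895,131.84729,0.97,0.438,0.169,0.213,0.481,-0.043
16,2005/5/23,46.73658,131.71468,0.93,0.492,0.190,0.319,0.400,0.092
1,2006/6/2,46.96788,131.97277,1.00,0.521,0.153,0.327,0.531,-0.009
2,2006/6/2,46.96206,131.98901,0.97,0.569,0.167,0.322,0.600,-0.031
3,2006/6/2,46.93895,131.97432,1.00,0.565,0.166,0.328,0.524,0.041
6,2006/6/2,46.89826,131.98191,1.00,0.483,0.141,0.323,0.494,-0.011
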