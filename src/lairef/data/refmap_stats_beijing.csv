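ID,Date,Latitude,Longitude,Crop cover,Mean_LAI_U1,Uncertainty,Standard deviation,Mean_LAI_U2,Scaling difference
1,2004/4/1,40.22732,116.81093,0.94,0.439,0.117,0.229,0.422,0.017
3,2004/4/1,40.20461,116.35767,0.86,0.450,0.121,0.335,0.428,0.022
12,2004/4/1,40.17907,116.56123,0.93,0.505,0.135,0.313,0.548,-0.042
13,2004/4/1,39.766,116.71623,0.90,0.484,0.130,0.266,0.457,0.028
1,2004/4/17,40.2273,116.81019,0.94,0.916,0.230,0.790,0.785,0.130
4,2004/4/17,40.20432,116.358,0.87,1.009,0.253,0.869,1.003,0.006
10,2004/4/17,40.17932,116.5612,0.93,1.111,0.279,0.939,1.191,-0.080
13,2004/4/17,39.76626,116.71829,0.90,0.793,0.199,0.493,0.799,-0.006
1,2004/5/19,40.22867,116.81305,0.94,1.108,0.230,0.772,1.044,0.064
3,2004/5/19,40.20434,116.35803,0.87,1.275,0.265,1.049,1.659,-0.384
11,2004/5/19,40.17934,116.56123,0.93,1.292,0.269,0.935,1.315,-0.023
14,2004/5/19,39.76601,116.71798,0.90,0.943,0.196,0.623,0.895,0.048
8,2005/4/4,40.17293,116.58101,0.96,0.467,0.207,0.294,0.404,0.063
14,2005/4/4,39.76601,116.71658,0.90,0.293,0.130,0.171,0.313,-0.020
15,2005/4/4,39.73602,116.72371,0.91,0.325,0.144,0.126,0.299,0.026
17,2005/4/4,39.67929,116.73827,0.89,0.273,0.121,0.145,0.271,0.002
8,2005/5/6,40.17293,116.58101,0.96,1.899,0.403,1.347,1.730,0.169
14,2005/5/6,39.76601,116.71658,0.90,1.311,0.278,1.052,1.264,0.047
15,2005/5/6,39.73602,116.72371,0.91,2.223,0.471,1.166,1.936,0.286
17,2005/5/6,39.67929,116.73827,0.89,1.782,0.378,1.408,1.525,0.257
8,2005/5/22,40.17293,116.58101,0.96,2.072,0.531,1.137,1.905,0.167
14,2005/5/22,39.76601,116.71658,0.90,1.435,0.367,0.909,1.463,-0.028
15,2005/5/22,39.73602,116.72371,0.91,2.257,0.578,0.987,2.033,0.223
17,2005/5/22,39.67929,116.73827,0.89,1.711,0.438,1.034,1.543,0.169
8,2006/4/7,40.17102,116.57608,1.00,1.125,0.350,0.794,1.045,0.079
15,2006/4/7,39.76628,116.71763,0.90,0.816,0.254,0.404,0.792,0.024
16,2006/4/7,39.73629,116.7237,0.91,1.160,0.361,0.508,1.105,0.055
18,2006/4/7,39.67902,116.73828,0.89,0.962,0.299,0.544,0.902,0.060
2,2007/4/10,40.17182,116.5722,1.00,1.433,0.385,0.914,1.408,0.025
14,2007/4/10,39.76628,116.71938,0.90,1.104,0.297,0.569,1.137,-0.033
18,2007/4/10,39.73575,116.72406,0.91,1.792,0.482,0.985,1.838,-0.046
20,2007/4/10,39.67794,116.73828,0.89,1.461,0.393,1.015,1.303,0.157
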