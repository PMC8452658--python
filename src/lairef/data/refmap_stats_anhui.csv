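ID,Date,Latitude,Longitude,Crop cover,Mean_LAI_U1,Uncertainty,Standard deviation,Mean_LAI_U2,Scaling difference
1,2017/3/29,33.151,116.772,0.95,4.651,1.079,2.040,2.833,1.818
3,2017/3/29,33.116,116.804,0.98,4.435,1.029,1.511,3.980,0.455
5,2017/3/29,33.100,116.865,0.82,2.190,0.508,1.423,1.925,0.265
12,2017/3/29,33.087,116.899,0.99,2.312,0.536,1.324,1.987,0.325
1,2017/4/23,33.151,116.772,0.95,4.055,0.657,1.730,3.474,0.581
3,2017/4/23,33.116,116.804,0.98,4.457,0.722,1.235,4.141,0.316
8,2017/4/23,33.100,116.865,0.82,2.665,0.432,1.613,2.285,0.379
15,2017/4/23,33.087,116.899,0.99,3.200,0.518,1.352,2.919,0.281
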