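date,site,k_ndvi,amplitude,ndvi_inf
2004/4/1,BJ-wheat,1.58,0.78,0.93
2004/4/17,BJ-wheat,1.49,0.96,0.97
2004/5/19,BJ-wheat,1.44,0.96,0.97
2005/4/4,BJ-wheat,1.30,0.86,0.97
2005/5/6,BJ-wheat,1.46,0.834,0.93
2005/5/22,BJ-wheat,1.42,0.96,0.97
2006/4/7,BJ-wheat,1.36,0.96,0.97
2007/4/10,BJ-wheat,1.48,0.96,0.97
2003/3/30,HN-wheat,1.58,0.96,0.97
2004/4/8,HN-wheat,1.66,0.96,0.97
2004/4/24,HN-wheat,1.62,0.96,0.97
2004/5/10,HN-wheat,1.59,0.91,0.96
2004/5/17,HN-wheat,1.44,0.76,0.91
2005/05/23,HLJ-barley,1.30,0.81,0.95
2006/06/02,HLJ-barley,1.30,0.944,0.97
2007/06/14,HLJ-barley,1.36,0.90,0.92
2005/05/23,HLJ-wheat,1.30,0.822,0.94
2006/06/02,HLJ-wheat,1.30,0.858,0.96
2017/3/29,AH-wheat,1.33,0.9400,0.95
2017/4/23,AH-wheat,1.80,0.9505,0.96
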