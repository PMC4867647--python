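top_cm,bottom_cm,bulk_density,sand,silt,clay,theta_r,theta_s,alpha,n,ks,pH
0,30,1.45,90,3,7,0.027,0.385,0.021,2.013,92,6.5
30,60,1.50,90,5,5,0.027,0.319,0.027,2.179,162,6.5
60,90,1.55,80,8,12,0.065,0.385,0.028,2.147,30,6.5
90,120,1.55,90,6,4,0.027,0.319,0.027,2.379,162,6.5
120,150,1.55,90,7,3,0.027,0.319,0.027,2.379,162,6.5
150,225,1.55,90,8,2,0.027,0.319,0.027,2.379,162,6.5
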