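name,tbase,tsum,ke,k_ini,k_mid,k_end,sla_max,sla_min,amax,r_max,emergence_a,emergence_b,xr_min,xr_med,xr_max,tr_min,tr_med,omega_c,max_uptake_rate
sugarbeet,0,2100,0.6,0.6,1.35,0.6,28,18,45,90,50,10,5,45,90,0,40,0.5,6
winter_wheat,0,2110,0.6,0.6,1.35,0.6,22,14,55,90,50,10,5,45,90,0,60,0.5,6
winter_barley,0,2000,0.6,0.6,1.35,0.6,25,18,45,90,50,10,5,45,90,0,60,0.5,6
winter_rye,0,1800,0.44,0.6,1.35,0.6,22,15,45,90,50,10,5,45,90,0,60,0.5,6
maize,8,1700,0.6,0.5,1.2,0.6,25,15,70,100,40,8,5,50,100,0,35,0.5,8
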