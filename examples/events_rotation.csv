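date,kind,amount,method,form,crop,sowing_depth,cn_ratio,incorporation_depth
2000-04-20,sow,0,,,maize,5.0,,
2000-05-10,fertilize,120,surface,urea,,,,
2000-06-15,irrigate,60,basin,,,,,
2000-06-15,fertilize,80,fertigation,urea,,,,
2000-07-20,irrigate,60,basin,,,,,
2000-09-25,harvest,0,,,,,,
2000-10-10,sow,0,,,winter_wheat,4.0,,
2000-10-10,fertilize,100,mix,ammonium,,,,
2001-03-25,fertilize,100,deep,urea,,,,
2001-04-10,irrigate,75,border,,,,,
2001-05-20,irrigate,75,border,,,,,
2001-07-15,harvest,0,,,,,,
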