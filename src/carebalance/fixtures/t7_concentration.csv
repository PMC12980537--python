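district,demand_score,resource_score,area_km2,demand_concentration,resource_concentration,ri
Liwan,0.6254,0.2500,59.1000,26.4904,0.0021,12916.8474
Yuexiu,0.9603,0.1777,33.8000,71.1228,0.0005,130993.2068
Haizhu,0.5458,0.0963,90.4000,15.1142,0.0014,10915.9028
Tianhe,0.2392,0.5576,96.3300,6.2161,0.0195,318.8836
Baiyun,0.1534,0.8481,795.7900,0.4826,0.3819,1.2635
Huangpu,0.0874,0.8446,484.1700,0.4519,0.4062,1.1126
Panyu,0.0951,0.4075,529.9400,0.4492,0.1971,2.2790
Huadu,0.0829,0.3756,970.0400,0.2139,0.3815,0.5607
Nansha,0.0885,0.4437,783.8600,0.2826,0.3412,0.8285
Conghua,0.0363,0.3514,1974.5000,0.0460,1.6593,0.0277
Zengcheng,0.0555,0.2492,1616.4700,0.0859,0.6301,0.1364
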