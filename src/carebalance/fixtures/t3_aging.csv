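district,year,aging_coefficient,aging_density,area_km2
Liwan,2015,24.49,2988,59.10
Liwan,2019,28.46,3640,59.10
Liwan,2023,31.13,4239,59.10
Yuexiu,2015,22.57,7845,33.80
Yuexiu,2019,26.18,9085,33.80
Yuexiu,2023,29.39,10175,33.80
Haizhu,2015,22.25,2487,90.40
Haizhu,2019,25.75,3039,90.40
Haizhu,2023,28.72,3526,90.40
Tianhe,2015,13.01,1141,96.33
Tianhe,2019,14.19,1423,96.33
Tianhe,2023,15.39,1747,96.33
Baiyun,2015,16.41,189,795.79
Baiyun,2019,16.7,227,795.79
Baiyun,2023,17.23,266,795.79
Huangpu,2015,14.03,127,484.17
Huangpu,2019,13.19,153,484.17
Huangpu,2023,12.93,188,484.17
Panyu,2015,13.55,219,529.94
Panyu,2019,13.71,267,529.94
Panyu,2023,14.31,325,529.94
Huadu,2015,15.22,111,970.04
Huadu,2019,15.32,128,970.04
Huadu,2023,15.45,144,970.04
Nansha,2015,16.43,80,783.86
Nansha,2019,16.14,95,783.86
Nansha,2023,15.95,115,783.86
Conghua,2015,12.42,39,1974.50
Conghua,2019,13.5,44,1974.50
Conghua,2023,15.06,51,1974.50
Zengcheng,2015,14.16,76,1616.47
Zengcheng,2019,14.15,86,1616.47
Zengcheng,2023,14.44,100,1616.47
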