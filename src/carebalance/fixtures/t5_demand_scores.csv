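district,score_2015,score_2019,score_2023,mean,rank
Liwan,0.5914,0.6444,0.6254,0.6204,2
Yuexiu,0.9548,0.9392,0.9603,0.9514,1
Haizhu,0.4936,0.5413,0.5458,0.5269,3
Tianhe,0.2063,0.1982,0.2392,0.2146,4
Baiyun,0.1771,0.1574,0.1534,0.1626,5
Huangpu,0.1192,0.0723,0.0874,0.0930,7
Panyu,0.1038,0.0792,0.0951,0.0927,8
Huadu,0.1092,0.0912,0.0829,0.0944,6
Nansha,0.1249,0.1021,0.0885,0.1052,9
Conghua,0.0001,0.0072,0.0363,0.0145,11
Zengcheng,0.0653,0.0462,0.0555,0.0557,10
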