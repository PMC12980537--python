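district,infrastructure,community,comprehensive,medical,composite,rank
Liwan,0.5391,0.1438,0.1977,0.0327,0.2500,8
Yuexiu,0.0222,0.1434,0.0001,0.4784,0.1777,10
Haizhu,0.1766,0.0604,0.0294,0.1469,0.0963,11
Tianhe,0.1985,0.3960,0.3794,0.8698,0.5576,3
Baiyun,0.8707,0.3785,0.7194,0.8243,0.8481,1
Huangpu,0.8311,0.7822,0.6739,0.4830,0.8446,2
Panyu,0.3533,0.3451,0.4088,0.3011,0.4075,5
Huadu,0.3431,0.1394,0.5737,0.2856,0.3756,6
Nansha,0.2925,0.4949,0.6527,0.1129,0.4437,4
Conghua,0.2630,0.5233,0.3039,0.1286,0.3514,7
Zengcheng,0.0517,0.2784,0.3057,0.2722,0.2492,9
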