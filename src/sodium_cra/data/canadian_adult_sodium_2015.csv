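sex,age_group,n,baseline_mean_mg,baseline_sd_mg,scenarioA_mean_mg,scenarioA_sd_mg
total,1-71+,20176,2758,2997,2299,1733
male,19-30,882,2983,1886,2485,1200
male,31-50,2077,3036,1910,2529,757
male,51-70,2246,3103,2081,2585,991
male,71+,1246,3196,1596,2662,455
female,19-30,897,2236,1438,1866,719
female,31-50,2288,2333,1445,1948,2373
female,51-70,2420,2467,1373,2059,585
female,71+,1556,2525,1519,2108,1144
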