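myc_group,measure,comparison,increase,no_increase
positive,mtv,baseline_vs_ipet,2,21
positive,mtv,ipet_vs_eot,21,5
positive,mtv,baseline_vs_eot,9,17
positive,suv,baseline_vs_ipet,4,19
positive,suv,ipet_vs_eot,21,5
positive,suv,baseline_vs_eot,11,15
negative,mtv,baseline_vs_ipet,0,30
negative,mtv,ipet_vs_eot,8,11
negative,mtv,baseline_vs_eot,1,18
negative,suv,baseline_vs_ipet,1,29
negative,suv,ipet_vs_eot,6,13
negative,suv,baseline_vs_eot,2,17
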