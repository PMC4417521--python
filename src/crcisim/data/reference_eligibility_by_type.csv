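household_type,prevalence_pct,no_services_pct,one_service_pct,two_services_pct,three_services_pct,four_plus_pct
Single person (16 to 64),17.59,43.3,36.1,14.2,5.1,1.3
Single person (65 plus),12.49,0.0,75.2,21.4,3.2,0.3
"Married (at least one < 65), no children",17.36,13.4,30.1,26.4,16.2,13.9
"Married (65 plus), no children",8.17,0.0,0.0,24.7,27.9,47.3
Married with one dependent child,8.34,1.1,13.3,27.6,26.3,31.7
Married with two or more dependent children,12.04,0.4,3.2,9.1,17.7,69.7
Married with only non-dependent child(ren),6.25,3.9,13.6,20.9,22.3,39.3
Lone mothers with one dependent child,3.44,1.9,20.2,35.6,21.8,20.5
Lone mothers with two or more dependent children,2.72,0.0,4.4,14.5,19.3,61.7
Lone mothers with only non-dependent child(ren),2.10,9.5,24.5,29.8,19.0,17.1
Lone fathers with one dependent child,0.43,7.0,38.4,27.9,12.8,14.0
Lone fathers with two or more dependent children,0.35,1.4,5.8,17.4,27.5,47.8
Lone fathers with only non-dependent child(ren),1.34,23.2,33.7,27.0,12.0,4.1
"Same-sex partnerships, no children",0.26,27.5,19.6,33.3,7.8,11.8
Same-sex partnerships with child(ren),0.01,0.0,0.0,0.0,50.0,50.0
Other households with one dependent child,0.97,0.0,0.5,8.2,20.1,71.1
Other households with more than one dependent child,0.87,0.0,0.0,0.6,6.4,93.1
"Student households, all students",0.55,10.1,22.9,23.9,20.2,22.9
Other households (all 65 plus),0.29,0.0,0.0,21.1,36.8,42.1
Other households (not all 65 plus),4.48,15.4,21.9,24.4,16.3,22.0
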