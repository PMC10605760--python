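# Abridged all-cause life table, Thailand 2019 (both sexes).
# Annualized band probabilities; synthetic approximation of the
# WHO Global Health Observatory abridged table (see docs/methods.md).
age,q_annual
0,0.007800
1,0.000375
5,0.000220
10,0.000260
15,0.000661
20,0.000962
25,0.001042
30,0.001203
35,0.001605
40,0.002270
45,0.003302
50,0.004847
55,0.007285
60,0.010728
65,0.016175
70,0.025420
75,0.042170
80,0.071042
85,0.150000
90,0.215000
95,0.295000
100,0.385000
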