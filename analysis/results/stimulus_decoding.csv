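stage,direction_acc,direction_pct95,speed_acc,speed_pct95
T1,1.0,0.9550395256916996,0.8125,0.6322916666666666
T2,1.0,0.6325757575757576,0.85,0.6666666666666666
T3,1.0,0.5667307692307691,1.0,0.622048611111111
T4,0.9435897435897436,0.5757692307692307,1.0,0.6179166666666666
T5,0.573076923076923,0.5782371794871795,1.0,0.5736931818181817
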