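stage,prestim_acc,report_acc,report_below_chance,report_pct5
T1,0.7066666666666667,0.15333333333333332,True,0.3666666666666667
T2,0.7,0.2933333333333334,True,0.42000000000000004
T3,0.6799999999999999,0.18,True,0.38666666666666666
T4,0.6666666666666666,0.21333333333333332,True,0.4
T5,0.6333333333333334,0.24666666666666667,True,0.38
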