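stage,onset_s,onset_before_reward_s,test_start_s,report_start_s,planted_lead_s
T1,3.0,0.4288343558282204,2.116564417177914,3.1288343558282206,0.0
T2,2.8000000000000003,0.6288343558282201,2.116564417177914,3.1288343558282206,0.5
T3,2.4000000000000004,1.02883435582822,2.116564417177914,3.1288343558282206,1.0
T4,4.2,1.130674846625766,4.01840490797546,5.030674846625766,1.5
T5,4.1000000000000005,1.2306748466257655,4.01840490797546,5.030674846625766,2.0
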