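stage,factor,delta_aic,aic_full,aic_partial,n_removed
T1,pre_stimulus,13103.403859988008,6804.662478288872,19908.06633827688,1
T1,lick_pre,116.32176659017568,6804.662478288872,6920.984244879048,1
T1,post_trial,7.280772207526752,6804.662478288872,6811.943250496399,1
T1,stimulus_direction,7.083865562568462,6804.662478288872,6811.7463438514405,2
T1,lick_post,0.0,6804.662478288872,6804.662478288872,1
T1,reward,-1.7014159604386805,6804.662478288872,6802.961062328433,1
T2,pre_stimulus,14037.37716191842,6931.245793077718,20968.62295499614,1
T2,lick_pre,108.63970592449914,6931.245793077718,7039.885499002217,1
T2,post_trial,6.3072706371558525,6931.245793077718,6937.553063714874,1
T2,stimulus_direction,1.657416234482298,6931.245793077718,6932.9032093122005,2
T2,lick_post,5.543497536564246e-07,6931.245793077718,6931.245793632068,1
T2,reward,0.0,6931.245793077718,6931.245793077718,1
T3,pre_stimulus,13952.67812671043,6906.878522195224,20859.556648905655,1
T3,lick_pre,71.95031998113882,6906.878522195224,6978.828842176363,1
T3,post_trial,9.527899816312129,6906.878522195224,6916.406422011536,1
T3,stimulus_direction,1.348512487289554,6906.878522195224,6908.2270346825135,2
T3,lick_post,-3.4694494388531893e-07,6906.878522195224,6906.878521848279,1
T3,reward,-1.9777838562658872,6906.878522195224,6904.900738338958,1
T4,pre_stimulus,22927.66531443239,10797.13725318004,33724.80256761243,1
T4,lick_pre,102.92739398123376,10797.13725318004,10900.064647161274,1
T4,post_trial,7.9169531341976835,10797.13725318004,10805.054206314238,1
T4,lick_post,0.0,10797.13725318004,10797.13725318004,1
T4,reward,0.0,10797.13725318004,10797.13725318004,1
T4,stimulus_direction,-2.404496041821403,10797.13725318004,10794.73275713822,2
T5,pre_stimulus,25206.889479122234,12488.4544280262,37695.34390714843,1
T5,lick_pre,67.14905277570142,12488.4544280262,12555.603480801901,1
T5,post_trial,13.09049252937075,12488.4544280262,12501.54492055557,1
T5,stimulus_direction,0.19095849088262185,12488.4544280262,12488.645386517082,2
T5,lick_post,0.0,12488.4544280262,12488.4544280262,1
T5,reward,-1.9410603582637123,12488.4544280262,12486.513367667936,1
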