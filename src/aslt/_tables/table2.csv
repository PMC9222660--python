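index,component,temp_C,k_zero,R2_zero,RMSE_zero,k_first,R2_first,RMSE_first
total_acid,whole,25,-0.0078,0.8699,0.3384,,,
total_acid,whole,35,-0.0083,0.9523,0.0958,-0.0015,0.9494,0.0968
total_acid,whole,45,-0.0196,0.9684,0.0943,-0.0034,0.9738,0.0888
L*,radish,25,0.0424,0.9325,1.3799,,,
L*,radish,35,0.1035,0.9424,1.2946,0.0022,0.9657,1.1442
L*,radish,45,0.2276,0.9029,2.0287,0.005,0.9468,1.7736
L*,vegetable,25,0.0238,0.8906,0.921,,,
L*,vegetable,35,0.0536,0.9274,0.7635,0.0012,0.9202,0.7807
L*,vegetable,45,0.1346,0.9188,1.0812,0.003,0.9265,1.0507
hardness,radish,25,1.711,0.9694,34.0525,,,
hardness,radish,35,4.3592,0.9669,40.4722,0.0097,0.8781,54.3007
hardness,radish,45,6.6641,0.8761,70.3778,0.0019,0.9596,49.5786
hardness,vegetable,25,0.585,0.984,8.8842,,,
hardness,vegetable,35,1.4207,0.9063,23.5509,0.0114,0.9967,11.6397
hardness,vegetable,45,2.7775,0.9116,23.0117,0.0219,0.9749,11.5778
sensory_score,whole,25,0.0212,0.9895,0.2086,,,
sensory_score,whole,35,0.0427,0.9713,0.2951,0.0079,0.9243,0.3661
sensory_score,whole,45,0.1075,0.9685,0.3111,0.018,0.8772,0.4704
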