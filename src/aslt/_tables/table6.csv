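index,component,Ea_kJ_mol,kref_d,R2_arrhenius,RMSE_arrhenius,dH_kJ_mol,dS_J_mol_K,R2_eyring,RMSE_eyring
total_acid,whole,47.23,-1.0616,0.9567,0.0018,,,,
L*,radish,65.18,0.1024,0.9943,0.001,62.6,-60.98,0.9942,0.001
L*,vegetable,72.09,0.0554,0.9995,0.0017,69.51,-43.66,0.9995,0.0017
hardness,radish,45.76,3.8813,0.9075,0.3766,43.19,-93.75,0.9075,0.3774
hardness,vegetable,58.1,1.3682,0.9779,0.0443,55.52,-62.38,0.9778,0.0446
sensory_score,whole,70.07,0.0453,0.9955,0.0024,67.48,-51.92,0.9995,0.0023
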