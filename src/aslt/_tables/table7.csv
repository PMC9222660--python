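index,component,A0,kref,Ea_J_mol,direction
total_acid,whole,4.96,1076000.0,47230.0,increasing
L*,radish,58.57,11470000000.0,65180.0,decreasing
L*,vegetable,49.22,92200000000.0,72090.0,decreasing
hardness,radish,763.28,222100000.0,45760.0,decreasing
hardness,vegetable,277.87,9673000000.0,58100.0,decreasing
sensory_score,whole,8.11,34120000000.0,70070.0,decreasing
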