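indicator,treatment,value,value_before,soil_total_hm,metal
pH,control,7.27,,,
SOM,control,18.21,,,
CEC,control,13.4,,,
A-N,control,29.4,,,
A-P,control,75.39,,,
A-K,control,40.56,,,
AHM,control,2.85,2.85,,Cd
biomass,control,1.16,,,
hm_above_ground,control,0.6,,5,Cd
hm_roots,control,2.3,,5,Cd
pH,RBC,7.22,,,
SOM,RBC,21.86,,,
CEC,RBC,13.4,,,
A-N,RBC,33.92,,,
A-P,RBC,79.01,,,
A-K,RBC,47.78,,,
AHM,RBC,2.14,2.85,,Cd
biomass,RBC,1.26,,,
hm_above_ground,RBC,0.4,,5,Cd
hm_roots,RBC,1.95,,5,Cd
hm_amendment,RBC,0,,,
stability,RBC,>3,,,
pH,HAP,7.11,,,
SOM,HAP,19.37,,,
CEC,HAP,12.1,,,
A-N,HAP,25.66,,,
A-P,HAP,47.31,,,
A-K,HAP,127.81,,,
AHM,HAP,1.5,2.85,,Cd
biomass,HAP,1.66,,,
hm_above_ground,HAP,0.35,,5,Cd
hm_roots,HAP,1.8,,5,Cd
hm_amendment,HAP,0,,,
stability,HAP,>3,,,
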