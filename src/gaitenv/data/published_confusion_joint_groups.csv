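group,actual,FGW,US,DS,UW,DW
knee_flexors,FGW,74.1,3.7,0,14.8,7.4
knee_flexors,US,3.7,88.9,3.7,0,3.7
knee_flexors,DS,0,14.8,77.8,0,7.4
knee_flexors,UW,18.5,0,3.7,74.1,3.7
knee_flexors,DW,18.5,0,14.8,3.7,63
knee_extensors,FGW,77.8,3.7,0.0,3.7,14.8
knee_extensors,US,0.0,77.8,0.0,18.5,3.7
knee_extensors,DS,7.4,0.0,74.1,3.7,14.8
knee_extensors,UW,7.4,14.8,3.7,63.0,11.1
knee_extensors,DW,11.1,18.5,14.8,7.4,48.1
ankle_flexor,FGW,59.3,11.1,0.0,11.1,18.5
ankle_flexor,US,3.7,48.1,29.6,3.7,14.8
ankle_flexor,DS,0.0,3.7,81.5,3.7,11.1
ankle_flexor,UW,14.8,14.8,7.4,59.3,3.7
ankle_flexor,DW,7.4,11.1,7.4,7.4,66.7
ankle_extensors,FGW,88.9,0.0,0.0,7.4,3.7
ankle_extensors,US,7.4,92.6,0.0,0.0,0.0
ankle_extensors,DS,0.0,3.7,85.2,0.0,11.1
ankle_extensors,UW,11.1,0.0,0.0,88.9,0.0
ankle_extensors,DW,7.4,3.7,0.0,0.0,88.9
mtp_flexor,FGW,74.1,0.0,0.0,11.1,14.8
mtp_flexor,US,3.7,81.5,7.4,0.0,7.4
mtp_flexor,DS,11.1,7.4,55.6,7.4,18.5
mtp_flexor,UW,14.8,0.0,3.7,81.5,0.0
mtp_flexor,DW,22.2,7.4,18.5,7.4,44.4
mtp_extensor,FGW,25.9,11.1,11.1,14.8,37.0
mtp_extensor,US,7.4,51.9,29.6,11.1,0.0
mtp_extensor,DS,18.5,11.1,48.1,11.1,11.1
mtp_extensor,UW,22.2,11.1,25.9,40.7,0.0
mtp_extensor,DW,18.5,11.1,11.1,0.0,59.3
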