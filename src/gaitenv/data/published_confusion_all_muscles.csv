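actual,FGW,US,DS,UW,DW
FGW,100,0,0,0,0
US,0,100,0,0,0
DS,0,0,96.3,0,3.7
UW,3.7,0,0,96.3,0
DW,0,3.7,3.7,3.7,88.9
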