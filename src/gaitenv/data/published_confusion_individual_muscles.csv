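muscle,actual,FGW,US,DS,UW,DW
RF,FGW,74.1,18.5,0.0,3.7,3.7
RF,US,0.0,92.6,0.0,3.7,3.7
RF,DS,0.0,3.7,55.6,29.6,11.1
RF,UW,3.7,11.1,7.4,55.6,22.2
RF,DW,11.1,3.7,14.8,11.1,59.3
VL,FGW,66.7,7.4,7.4,14.8,3.7
VL,US,0.0,77.8,0.0,22.2,0.0
VL,DS,3.7,0.0,55.6,7.4,33.3
VL,UW,11.1,3.7,3.7,33.3,25.9
VL,DW,14.8,3.7,11.1,18.5,51.9
VM,FGW,92.6,0.0,0.0,3.7,3.7
VM,US,0.0,77.8,0.0,22.2,3.7
VM,DS,0.0,0.0,59.3,7.4,33.3
VM,UW,11.1,14.8,0.0,59.3,14.8
VM,DW,3.7,3.7,14.8,22.2,55.6
ST,FGW,74.1,0.0,0.0,7.4,18.5
ST,US,7.4,77.8,7.4,3.7,3.7
ST,DS,0.0,22.2,66.7,0.0,11.1
ST,UW,3.7,7.4,0.0,88.9,0.0
ST,DW,29.6,7.4,3.7,3.7,55.6
BF,FGW,59.3,3.7,18.5,0.0,18.5
BF,US,7.4,63.0,7.4,3.7,18.5
BF,DS,3.7,7.4,70.4,11.1,7.4
BF,UW,7.4,3.7,3.7,85.2,0.0
BF,DW,7.4,14.8,14.8,7.4,55.6
MG,FGW,85.2,0.0,0.0,11.1,3.7
MG,US,3.7,96.3,0.0,0.0,0.0
MG,DS,0.0,0.0,63.0,0.0,37.0
MG,UW,11.1,3.7,0.0,85.2,0.0
MG,DW,14.8,0.0,7.4,0.0,77.8
LG,FGW,70.4,3.7,7.4,14.8,3.7
LG,US,7.4,88.9,0.0,0.0,3.7
LG,DS,7.4,0.0,66.7,3.7,22.2
LG,UW,7.4,0.0,3.7,88.9,0.0
LG,DW,0.0,0.0,25.9,3.7,70.4
Sol,FGW,55.6,3.7,7.4,25.9,7.4
Sol,US,7.4,85.2,3.7,3.7,0.0
Sol,DS,11.1,0.0,70.4,0.0,18.5
Sol,UW,14.8,3.7,3.7,74.1,3.7
Sol,DW,14.8,3.7,22.2,3.7,55.6
TA,FGW,59.3,11.1,0.0,11.1,18.5
TA,US,3.7,48.1,29.6,3.7,14.8
TA,DS,0.0,3.7,81.5,3.7,11.1
TA,UW,14.8,14.8,7.4,59.3,3.7
TA,DW,7.4,11.1,7.4,7.4,66.7
FHL,FGW,74.1,0.0,0.0,11.1,14.8
FHL,US,3.7,81.5,7.4,0.0,7.4
FHL,DS,11.1,7.4,55.6,7.4,18.5
FHL,UW,14.8,0.0,3.7,81.5,0.0
FHL,DW,22.2,7.4,18.5,7.4,44.4
EDL,FGW,25.9,11.1,11.1,14.8,37.0
EDL,US,7.4,51.9,29.6,11.1,0.0
EDL,DS,18.5,11.1,48.1,11.1,11.1
EDL,UW,22.2,11.1,25.9,40.7,0.0
EDL,DW,18.5,11.1,11.1,0.0,59.3
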