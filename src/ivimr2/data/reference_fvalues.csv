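quantity,group,across,F,P
volume,Group A,timepoints,225.693,0.001
volume,Group B,timepoints,138.571,0.001
volume,Group C,timepoints,163.686,0.001
volume,Group D,timepoints,49.422,0.001
D,Group A,timepoints,2.112,0.121
D,Group B,timepoints,88.564,0.001
D,Group C,timepoints,64.248,0.001
D,Group D,timepoints,227.398,0.001
Dstar,Group A,timepoints,12.594,0.001
Dstar,Group B,timepoints,3.643,0.025
Dstar,Group C,timepoints,2.792,0.059
Dstar,Group D,timepoints,5.307,0.005
f,Group A,timepoints,14.785,0.001
f,Group B,timepoints,8.778,0.001
f,Group C,timepoints,6.66,0.002
f,Group D,timepoints,0.479,0.699
R2star,Group A,timepoints,15.297,0.001
R2star,Group B,timepoints,5.421,0.005
R2star,Group C,timepoints,11.17,0.001
R2star,Group D,timepoints,136.315,0.001
HIF1a,,groups,37.969,0.001
Ki67,,groups,47.414,0.001
TUNEL,,groups,55.906,0.001
PTEN,,groups,77.738,0.001
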