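quantity,unit,group,timepoint,mean,sd,n
volume,mm^3,Group A,base,217.5,60.1,8
volume,mm^3,Group A,week1,436.3,59.6,8
volume,mm^3,Group A,week2,702.5,42.9,8
volume,mm^3,Group A,week3,1039.8,93.9,8
volume,mm^3,Group B,base,226.4,38.9,8
volume,mm^3,Group B,week1,360.6,45.6,8
volume,mm^3,Group B,week2,522.0,69.2,8
volume,mm^3,Group B,week3,792.4,72.8,8
volume,mm^3,Group C,base,226.0,45.3,8
volume,mm^3,Group C,week1,380.5,45.1,8
volume,mm^3,Group C,week2,588.1,53.4,8
volume,mm^3,Group C,week3,757.6,60.6,8
volume,mm^3,Group D,base,226.9,48.3,8
volume,mm^3,Group D,week1,311.1,41.9,8
volume,mm^3,Group D,week2,377.5,56.9,8
volume,mm^3,Group D,week3,547.4,68.0,8
D,1e-3 mm^2/s,Group A,base,0.556,0.024,8
D,1e-3 mm^2/s,Group A,week1,0.564,0.017,8
D,1e-3 mm^2/s,Group A,week2,0.546,0.029,8
D,1e-3 mm^2/s,Group A,week3,0.536,0.022,8
D,1e-3 mm^2/s,Group B,base,0.562,0.030,8
D,1e-3 mm^2/s,Group B,week1,0.628,0.023,8
D,1e-3 mm^2/s,Group B,week2,0.699,0.028,8
D,1e-3 mm^2/s,Group B,week3,0.800,0.039,8
D,1e-3 mm^2/s,Group C,base,0.555,0.019,8
D,1e-3 mm^2/s,Group C,week1,0.608,0.031,8
D,1e-3 mm^2/s,Group C,week2,0.695,0.032,8
D,1e-3 mm^2/s,Group C,week3,0.778,0.050,8
D,1e-3 mm^2/s,Group D,base,0.566,0.026,8
D,1e-3 mm^2/s,Group D,week1,0.762,0.026,8
D,1e-3 mm^2/s,Group D,week2,0.868,0.021,8
D,1e-3 mm^2/s,Group D,week3,0.930,0.043,8
Dstar,1e-3 mm^2/s,Group A,base,8.53,0.57,8
Dstar,1e-3 mm^2/s,Group A,week1,8.87,0.82,8
Dstar,1e-3 mm^2/s,Group A,week2,9.81,0.61,8
Dstar,1e-3 mm^2/s,Group A,week3,10.25,0.52,8
Dstar,1e-3 mm^2/s,Group B,base,8.49,0.50,8
Dstar,1e-3 mm^2/s,Group B,week1,8.43,0.60,8
Dstar,1e-3 mm^2/s,Group B,week2,8.79,0.68,8
Dstar,1e-3 mm^2/s,Group B,week3,9.45,0.91,8
Dstar,1e-3 mm^2/s,Group C,base,8.59,0.44,8
Dstar,1e-3 mm^2/s,Group C,week1,8.47,0.58,8
Dstar,1e-3 mm^2/s,Group C,week2,8.91,0.52,8
Dstar,1e-3 mm^2/s,Group C,week3,9.07,0.27,8
Dstar,1e-3 mm^2/s,Group D,base,8.53,0.45,8
Dstar,1e-3 mm^2/s,Group D,week1,7.54,0.48,8
Dstar,1e-3 mm^2/s,Group D,week2,7.87,0.60,8
Dstar,1e-3 mm^2/s,Group D,week3,8.04,0.50,8
f,%,Group A,base,16.75,0.95,8
f,%,Group A,week1,17.71,0.83,8
f,%,Group A,week2,18.60,0.74,8
f,%,Group A,week3,19.15,0.50,8
f,%,Group B,base,16.69,0.69,8
f,%,Group B,week1,17.45,0.71,8
f,%,Group B,week2,17.51,0.73,8
f,%,Group B,week3,18.60,0.86,8
f,%,Group C,base,16.74,0.79,8
f,%,Group C,week1,17.11,0.55,8
f,%,Group C,week2,18.01,0.83,8
f,%,Group C,week3,18.25,0.94,8
f,%,Group D,base,16.70,0.51,8
f,%,Group D,week1,16.59,0.65,8
f,%,Group D,week2,16.81,0.88,8
f,%,Group D,week3,16.96,0.51,8
R2star,1/s,Group A,base,24.74,0.61,8
R2star,1/s,Group A,week1,25.44,0.75,8
R2star,1/s,Group A,week2,26.41,0.65,8
R2star,1/s,Group A,week3,26.98,0.85,8
R2star,1/s,Group B,base,24.79,0.64,8
R2star,1/s,Group B,week1,23.46,1.14,8
R2star,1/s,Group B,week2,22.86,1.50,8
R2star,1/s,Group B,week3,22.58,1.33,8
R2star,1/s,Group C,base,24.60,1.08,8
R2star,1/s,Group C,week1,23.00,1.87,8
R2star,1/s,Group C,week2,22.04,1.18,8
R2star,1/s,Group C,week3,21.11,0.55,8
R2star,1/s,Group D,base,24.74,0.65,8
R2star,1/s,Group D,week1,21.41,0.81,8
R2star,1/s,Group D,week2,19.64,0.72,8
R2star,1/s,Group D,week3,17.30,0.84,8
HIF1a,%,Group A,week3,83.1,10.8,8
HIF1a,%,Group B,week3,68.6,7.9,8
HIF1a,%,Group C,week3,60.5,8.3,8
HIF1a,%,Group D,week3,39.3,5.7,8
Ki67,%,Group A,week3,68.5,6.0,8
Ki67,%,Group B,week3,54.6,5.7,8
Ki67,%,Group C,week3,47.9,5.1,8
Ki67,%,Group D,week3,35.1,5.9,8
TUNEL,%,Group A,week3,25.6,5.9,8
TUNEL,%,Group B,week3,50.8,7.6,8
TUNEL,%,Group C,week3,56.9,9.1,8
TUNEL,%,Group D,week3,75.1,8.1,8
PTEN,%,Group A,week3,26.1,5.4,8
PTEN,%,Group B,week3,44.1,5.7,8
PTEN,%,Group C,week3,51.8,6.7,8
PTEN,%,Group D,week3,79.0,9.6,8
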