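# Symmetric typical-path airway geometry (Weibel-A dimensional model, adult,
# total lung volume ~4800 mL).  Dimensions are isotropically rescaled at run
# time to the subject's functional residual capacity.
# region: TB = tracheobronchial (conducting), AL = alveolated (respiratory).
# branch_angle_deg: mean branching angle used by the impaction kernel.
# gravity_angle_deg: mean inclination of the airway axis to the horizontal,
# used by the sedimentation kernel (cos of this angle).
generation,count,diameter_cm,length_cm,branch_angle_deg,gravity_angle_deg,region
0,1,1.800,12.000,0,90,TB
1,2,1.220,4.760,33,60,TB
2,4,0.830,1.900,34,60,TB
3,8,0.560,0.760,35,60,TB
4,16,0.450,1.270,36,60,TB
5,32,0.350,1.070,37,60,TB
6,64,0.280,0.900,38,60,TB
7,128,0.230,0.760,39,60,TB
8,256,0.186,0.640,40,60,TB
9,512,0.154,0.540,41,60,TB
10,1024,0.130,0.460,42,60,TB
11,2048,0.109,0.390,43,60,TB
12,4096,0.095,0.330,44,60,TB
13,8192,0.082,0.270,45,60,TB
14,16384,0.074,0.230,45,60,TB
15,32768,0.066,0.200,45,60,TB
16,65536,0.060,0.165,45,60,TB
17,131072,0.054,0.141,45,60,AL
18,262144,0.050,0.117,45,60,AL
19,524288,0.047,0.099,45,60,AL
20,1048576,0.045,0.083,45,60,AL
21,2097152,0.043,0.070,45,60,AL
22,4194304,0.041,0.059,45,60,AL
23,8388608,0.041,0.050,45,60,AL
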