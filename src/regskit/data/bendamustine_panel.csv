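cell_line,disease,t0,t0_lo,t0_hi,gi50,gi50_lo,gi50_hi,tgi,tgi_lo,tgi_hi,lc48,lc48_lo,lc48_hi,auc0,auc0_lo,auc0_hi
AMO-1,MM,30,29,31,1.84,1.83,1.84,1.91,1.91,1.92,2.01,2.00,2.02,350.77,344.73,357.66
DB,DLBCL,40,39,41,1.83,1.83,1.84,1.96,1.95,1.97,2.10,2.10,2.10,344.57,338.43,347.85
FARAGE,DLBCL,48,46,50,0.99,0.96,1.01,1.37,1.34,1.39,1.58,1.57,1.59,269.60,258.59,273.48
HBL-1,DLBCL,32,31,32,1.46,1.44,1.47,1.63,1.62,1.64,1.81,1.80,1.82,313.61,308.36,316.95
KMS-11,MM,47,45,49,1.82,1.81,1.82,1.85,1.85,1.85,1.91,1.91,1.92,340.53,330.90,348.95
KMS-12-BM,MM,38,37,40,1.30,1.28,1.33,1.53,1.52,1.53,1.62,1.61,1.63,287.42,279.99,292.87
KMS-12-PE,MM,45,43,47,1.80,1.80,1.80,1.81,1.81,1.82,1.83,1.82,1.84,346.87,336.46,354.13
LP-1,MM,37,35,38,2.07,2.03,2.10,2.12,2.10,2.13,2.16,2.12,2.17,351.59,334.09,361.07
MC-116,DLBCL,59,55,62,1.56,1.52,1.57,1.75,1.71,1.78,1.81,1.81,1.81,288.97,274.71,294.63
MOLP-2,MM,129,119,141,0.99,0.94,1.01,1.20,1.16,1.22,1.80,1.77,1.80,250.41,237.85,261.82
MOLP-8,MM,32,31,33,1.27,1.25,1.28,1.50,1.47,1.52,1.75,1.72,1.78,297.54,293.42,302.04
NCI-H929,MM,43,42,45,1.80,1.80,1.80,1.83,1.80,1.83,1.88,1.81,1.89,340.65,326.74,346.13
NU-DHL-1,DLBCL,34,33,35,0.96,0.93,0.99,1.28,1.27,1.29,1.52,1.51,1.52,267.75,261.68,269.21
NU-DUL-1,DLBCL,43,42,44,0.60,0.60,0.61,0.73,0.72,0.74,0.96,0.95,0.97,228.13,226.01,235.19
OCI-Ly3,DLBCL,26,25,26,1.35,1.33,1.36,1.61,1.57,1.64,1.88,1.87,1.89,310.70,304.25,314.61
OCI-Ly7,DLBCL,44,42,46,1.54,1.53,1.55,1.69,1.67,1.71,1.83,1.82,1.84,269.17,262.78,278.12
OCI-Ly8,DLBCL,23,23,24,1.52,1.49,1.54,1.83,1.82,1.83,1.92,1.91,1.93,315.94,309.48,320.47
OPM-2,MM,69,66,73,1.82,1.81,1.83,1.88,1.87,1.89,2.06,2.05,2.07,342.42,329.41,350.07
RIVA,DLBCL,40,38,41,1.34,1.32,1.38,1.56,1.56,1.57,1.73,1.72,1.74,286.65,275.47,294.00
RPMI-8226,MM,43,41,46,2.10,2.10,2.11,2.10,2.10,2.14,2.11,2.11,2.21,378.98,369.63,382.48
SU-DHL-10,DLBCL,31,30,32,1.83,1.83,1.83,1.87,1.87,1.88,1.93,1.92,1.93,351.16,343.86,357.56
SU-DHL-5,DLBCL,35,34,37,0.44,0.43,0.45,0.62,0.62,0.63,0.78,0.78,0.79,219.79,213.34,223.48
SU-DHL-8,DLBCL,58,56,61,1.05,1.03,1.07,1.24,1.22,1.26,1.54,1.52,1.56,281.88,269.61,283.06
U266,MM,58,56,60,1.80,1.75,1.80,1.88,1.88,1.89,2.09,2.08,2.10,333.48,326.50,337.13
U-2932,DLBCL,46,43,47,1.16,1.13,1.19,1.37,1.35,1.39,1.68,1.67,1.70,288.84,280.70,293.88
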