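# Archival Next Generation Impactor stage calibration.
# d50_60lpm_um: stage cut-off aerodynamic diameter (um) at the 60 L/min reference flow.
# flow_exponent: x in d50(Q) = d50(60) * (60/Q)^x, valid over the calibrated flow window.
stage,d50_60lpm_um,flow_exponent
1,8.06,0.54
2,4.46,0.52
3,2.82,0.50
4,1.66,0.47
5,0.94,0.53
6,0.55,0.60
7,0.34,0.67
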