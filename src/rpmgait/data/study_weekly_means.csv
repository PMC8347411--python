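metric,week,mean,sd
oks,preop,25.60,8.83
oks,W3,30.46,8.20
oks,W6,36.46,6.91
oks,W12,38.92,7.50
eq5d_index,preop,0.63,0.191
eq5d_index,W6,0.83,0.152
eq5d_index,W12,0.86,0.152
eq_vas,preop,75.36,17.86
eq_vas,W12,87,9.53
bone_stimulus,W2,90.73,28.19
bone_stimulus,W6,138.21,19.70
impact_load,W2,1424.77,1637.87
impact_load,W6,5290.01,2606.97
asymmetry_pct,W2,-17.55,16.50
asymmetry_pct,W6,-10.62,15.88
six_mwt_m,preop,372.14,61.57
six_mwt_m,W6,417,136.32
max_flexion_deg,preop,91.45,1.401
max_flexion_deg,W6,99.25,9.59
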