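label,topology,bet_surface,size_min,size_max,ec50,ec50_sd,mic,zone_mm,bet_uncertainty
pure TiO_2,unmodified,154,0,0,>300,,>500,6,5
0.1Au,pure,168,8,31,187.50,0.43,>500,6,5
0.25Au,pure,139,12,63,118.39,2.19,>500,9,5
1.25Au,pure,140,12,129,156.80,0.42,>500,9,5
0.1Pd,pure,154,4,4.5,164.18,1.75,>500,6,5
0.25Pd,pure,182,4,11,186.35,1.73,>500,6,5
0.5Pd,pure,139,3,12,204.02,1.96,>500,6,5
0.5Pd_1.25Au,alloy,139,8,45,275.63,3.13,>500,6,5
0.1Pd_0.1Au,core_shell,156,6,25,165.96,0.76,>500,6,5
0.1Pd_0.25Au,alloy,157,63,140,158.00,0.92,>500,6,5
0.1Pd_0.5Au,alloy,148,54,200,195.73,1.82,>500,7,5
0.1Pd_1.25Au,alloy,179,5,17,155.35,2.38,>500,7,5
0.5Pd_0.1Au,core_shell,136,15,35,141.91,1.73,>500,6,5
0.5Pd_0.25Au,core_shell,164,19,40,175.12,1.91,>500,6,5
0.5Pd_0.5Au,core_shell,153,8,80,162.68,2.29,>500,7,5
0.25Pd_0.25Au,core_shell,159,17,170,134.28,1.35,>500,6,5
0.25Pd_0.5Au,alloy,158,7,70,241.73,3.07,>500,6,5
0.25Pd_1.25Au,core_shell,145,16,68,220.80,0.51,>500,6,5
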