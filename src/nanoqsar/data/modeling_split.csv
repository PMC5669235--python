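label,status,observed_ec50,predicted_ec50,bagging_predicted_ec50,prediction_error
1.25Au,training_bagging,156.80,162.38,165.33,5.58
0.25Pd,training,186.35,187.03,,0.68
0.1Pd_0.1Au,training_bagging,165.96,169.12,159.26,3.16
0.25Pd_1.25Au,training,162.68,169.91,,7.23
0.5Pd_1.25Au,training_bagging,275.63,264.60,197.37,11.03
0.1Pd_1.25Au,training,155.35,143.02,,12.33
0.25Au,training,118.39,126.65,,8.26
0.1Pd_0.5Au,training_bagging,195.73,199.78,171.02,4.05
0.25Pd_0.25Au,training_bagging,141.91,142.69,156.06,0.78
0.1Pd,training,164.18,163.35,,0.83
0.5Pd_0.25Au,training,241.73,224.70,,17.03
0.5Pd_0.1Au,training,134.28,150.21,,15.93
0.25Pd_0.5Au,test,175.12,170.42,,4.7
0.1Au,test,187.50,180.69,,6.81
0.5Pd_0.5Au,test,220.80,210.40,,10.4
0.1Pd_0.25Au,test,158.00,150.18,,7.82
0.5Pd,test,204.02,193.24,,10.78
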