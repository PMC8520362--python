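table,site,structure,plane,clock,g1_mean,g1_sd,g1_n,g2_mean,g2_sd,g2_n,printed_t,printed_p
covariates,age_years,,,,29.4,3.0,77,30.1,3.2,80,0.4,0.69
covariates,height_cm,,,,162.91,3.69,77,163.08,4.02,80,0.26,0.79
covariates,maternal_weight_kg,,,,68.78,4.53,77,69.51,2.85,80,1.2,0.23
covariates,newborn_weight_kg,,,,3.22,0.30,77,3.21,0.28,80,-0.23,0.82
IAS,IAS_proximal_3,IAS,proximal,3,2.05,0.54,77,2.21,0.67,80,1.6,0.11
IAS,IAS_proximal_6,IAS,proximal,6,1.86,0.53,77,2.11,0.76,80,2.32,0.02
IAS,IAS_proximal_9,IAS,proximal,9,2.15,0.57,77,2.17,0.58,80,0.21,0.83
IAS,IAS_proximal_12,IAS,proximal,12,1.53,0.60,77,1.78,0.55,80,2.7,<0.01
IAS,IAS_mid_3,IAS,mid,3,2.25,0.58,77,2.40,0.59,80,1.61,0.11
IAS,IAS_mid_6,IAS,mid,6,1.83,0.55,77,1.73,0.48,80,-1.19,0.23
IAS,IAS_mid_9,IAS,mid,9,2.33,0.51,77,2.53,0.61,80,2.31,0.02
IAS,IAS_mid_12,IAS,mid,12,1.65,0.63,77,2.01,0.57,80,3.7,<0.01
IAS,IAS_distal_3,IAS,distal,3,2.13,0.60,77,2.19,0.59,80,0.68,0.5
IAS,IAS_distal_6,IAS,distal,6,2.04,0.59,77,1.98,0.57,80,-0.76,0.45
IAS,IAS_distal_9,IAS,distal,9,2.23,0.51,77,2.37,0.54,80,1.67,0.1
IAS,IAS_distal_12,IAS,distal,12,1.55,0.56,77,1.72,0.60,80,1.82,0.07
EAS_PRM,EAS_distal_3,EAS,distal,3,2.93,0.82,77,2.87,0.80,80,-0.52,0.6
EAS_PRM,EAS_distal_6,EAS,distal,6,2.04,0.59,77,2.73,0.88,80,-0.48,0.63
EAS_PRM,EAS_distal_9,EAS,distal,9,3.12,0.84,77,3.23,0.77,80,0.8,0.43
EAS_PRM,EAS_distal_12,EAS,distal,12,1.04,0.27,77,1.87,0.55,80,12.15,<0.01
EAS_PRM,PRM_mid_4,PRM,mid,4,7.00,1.40,77,7.37,1.51,80,1.62,0.11
EAS_PRM,PRM_mid_8,PRM,mid,8,7.21,1.39,77,7.34,1.71,80,0.55,0.58
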