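# Per-arm evidence table for the advanced-melanoma immune-checkpoint-inhibitor
# network: 12 randomized trials, progression-free-survival hazard ratios with
# 95% CIs where reported.  "ref" marks the trial's reference arm; empty HR
# cells are trials that reported no usable PFS hazard ratio.  Adverse-event
# count columns are empty: per-arm AE counts were not published in usable form.
trial_id,author_year,treatment,n,hr,ci_low,ci_high,ae_any,ae_high,outcome,dose_label
weber2015,Weber 2015,NIV,272,0.82,0.32,2.05,,,PFS,nivolumab 3 mg/kg q2w
weber2015,Weber 2015,CHE,133,ref,,,,,PFS,investigator-choice chemotherapy
ribas2015,Ribas 2015,PEM,180,0.57,0.45,0.73,,,PFS,pembrolizumab 2 mg/kg
ribas2015,Ribas 2015,PEM,181,0.50,0.39,0.64,,,PFS,pembrolizumab 10 mg/kg
ribas2015,Ribas 2015,CHE,179,ref,,,,,PFS,investigator-choice chemotherapy
larkin2015,Larkin 2015,NIV,316,0.57,0.43,0.76,,,PFS,nivolumab 3 mg/kg q2w
larkin2015,Larkin 2015,IPI_NIV,314,0.42,0.31,0.57,,,PFS,ipilimumab 3 + nivolumab 1
larkin2015,Larkin 2015,IPI,315,ref,,,,,PFS,ipilimumab 3 mg/kg q3w
postow2015,Postow 2015,IPI_NIV,95,0.40,0.23,0.68,,,PFS,ipilimumab 3 + nivolumab 1
postow2015,Postow 2015,IPI,47,ref,,,,,PFS,ipilimumab 3 mg/kg q3w
robert2015a,Robert 2015 (pembrolizumab),PEM,279,0.58,0.46,0.72,,,PFS,pembrolizumab 10 mg/kg q2w
robert2015a,Robert 2015 (pembrolizumab),PEM,277,0.58,0.47,0.72,,,PFS,pembrolizumab 10 mg/kg q3w
robert2015a,Robert 2015 (pembrolizumab),IPI,278,ref,,,,,PFS,ipilimumab 3 mg/kg q3w
robert2015b,Robert 2015 (nivolumab),NIV,210,0.43,0.34,0.56,,,PFS,nivolumab 3 mg/kg q3w
robert2015b,Robert 2015 (nivolumab),CHE,208,ref,,,,,PFS,dacarbazine
hodi2014,Hodi 2014,IPI_SAR,123,0.87,0.64,1.18,,,PFS,ipilimumab 10 + sargramostim
hodi2014,Hodi 2014,IPI,122,ref,,,,,PFS,ipilimumab 10 mg/kg q3w
ribas2013,Ribas 2013,TRE,328,0.55,0.39,0.76,,,PFS,tremelimumab 15 mg/kg q90d
ribas2013,Ribas 2013,CHE,327,ref,,,,,PFS,investigator-choice chemotherapy
robert2011,Robert 2011,IPI_CHE,250,0.76,0.63,0.93,,,PFS,ipilimumab 10 + dacarbazine
robert2011,Robert 2011,CHE,252,ref,,,,,PFS,dacarbazine + placebo
hodi2010,Hodi 2010,IPI_GP100,403,0.81,0.74,0.92,,,PFS,ipilimumab 3 + gp100
hodi2010,Hodi 2010,IPI,137,0.64,0.56,0.78,,,PFS,ipilimumab 3 mg/kg q3w
hodi2010,Hodi 2010,GP100,136,ref,,,,,PFS,gp100 vaccine
hersh2011,Hersh 2011,IPI_CHE,35,,,,,,PFS,ipilimumab 3 + dacarbazine
hersh2011,Hersh 2011,IPI,37,,,,,,PFS,ipilimumab 3 mg/kg q4w
weber2009,Weber 2009,IPI_BUD,58,,,,,,PFS,ipilimumab 10 + budesonide
weber2009,Weber 2009,IPI,57,,,,,,PFS,ipilimumab 10 + placebo
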