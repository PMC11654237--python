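controls:
- analyte: IgA
  level: L1
  target_mean: 1.1
  target_sd: 0.033
- analyte: IgA
  level: L3
  target_mean: 4.1
  target_sd: 0.119
- analyte: AAT
  level: L1
  target_mean: 0.85
  target_sd: 0.041
- analyte: AAT
  level: L3
  target_mean: 2.4
  target_sd: 0.122
- analyte: Prealbumin
  level: L1
  target_mean: 0.18
  target_sd: 0.0077
- analyte: Prealbumin
  level: L3
  target_mean: 0.45
  target_sd: 0.019
- analyte: Lp(a)
  level: L1
  target_mean: 0.3
  target_sd: 0.015
- analyte: Lp(a)
  level: L3
  target_mean: 0.9
  target_sd: 0.046
- analyte: Cp
  level: L1
  target_mean: 0.2
  target_sd: 0.0076
- analyte: Cp
  level: L3
  target_mean: 0.55
  target_sd: 0.0198
peer:
- analyte: IgA
  level: L1
  group_mean: 1.0992300000000002
- analyte: IgA
  level: L3
  group_mean: 4.09713
- analyte: AAT
  level: L1
  group_mean: 0.844645
- analyte: AAT
  level: L3
  group_mean: 2.38488
- analyte: Prealbumin
  level: L1
  group_mean: 0.176976
- analyte: Prealbumin
  level: L3
  group_mean: 0.44244
- analyte: Lp(a)
  level: L1
  group_mean: 0.29328
- analyte: Lp(a)
  level: L3
  group_mean: 0.8798400000000001
- analyte: Cp
  level: L1
  group_mean: 0.19662000000000002
- analyte: Cp
  level: L3
  group_mean: 0.540705
tea:
- analyte: IgA
  z_score: 1.65
  imprecision_goal_pct: 7.07
  bias_goal_pct: 3.0
- analyte: AAT
  z_score: 1.65
  imprecision_goal_pct: 8.11
  bias_goal_pct: 3.0
- analyte: Prealbumin
  z_score: 1.65
  imprecision_goal_pct: 8.65
  bias_goal_pct: 3.0
- analyte: Lp(a)
  z_score: 1.65
  imprecision_goal_pct: 11.27
  bias_goal_pct: 3.0
- analyte: Cp
  z_score: 1.65
  imprecision_goal_pct: 6.1
  bias_goal_pct: 3.0
reporting_levels:
  IgA: L3
  AAT: L3
  Prealbumin: L1
  Lp(a): L1
  Cp: L3
phases:
- label: A
  start: 0
  stop: 22
  rules:
    IgA: 1_3s/R_4s/2_2s
    AAT: 1_3s/R_4s/2_2s
    Prealbumin: 1_3s/R_4s/2_2s
    Lp(a): 1_3s/R_4s/2_2s
    Cp: 1_3s/R_4s/2_2s
- label: B
  start: 22
  stop: 44
  rules:
    IgA: 1_3s/2_2s
    AAT: 1_3s/2_2s/R_4s/4_1s/10_x
    Prealbumin: 1_3s/2_2s/R_4s/4_1s/10_x
    Lp(a): 1_3s/2_2s/R_4s/4_1s/10_x
    Cp: 1_3s/2_2s/R_4s/4_1s/10_x
- label: C
  start: 44
  stop: 66
  rules:
    IgA: 1_3s/2_2s/R_4s/4_1s
    AAT: 1_3s/2_2s/R_4s/4_1s/10_x
    Prealbumin: 1_3s/2_2s/R_4s/4_1s/8_x
    Lp(a): 1_3s/2_2s/R_4s/4_1s
    Cp: 1_3s/2_2s/R_4s/4_1s/8_x
- label: D
  start: 66
  stop: 88
  rules:
    IgA: 1_3s
    AAT: 1_3s/2/3_2s/R_4s/3_1s/12_x
    Prealbumin: 1_3s/2_2s/R_4s/4_1s/8_x
    Lp(a): 1_3s/2_2s/R_4s/4_1s/10_x
    Cp: 1_3s/2/3_2s/R_4s/3_1s/12_x
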