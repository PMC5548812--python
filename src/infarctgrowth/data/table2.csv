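age,risk_factors,vessels,original_iv3,anfis_iv3,linear_iv3,log_iv3,exp_iv3,time_to_ct3_hours
66,"DM, CAD",MCA,326.32,307.32,126.19,272.7,82.15,21.3
38,HTN,MCA,348.82,407.58,205.59,334.54,236.17,48.3
53,"HTN, DyL","ICA, MCA, ACA",650,600.84,506.22,445.11,360.03,64.3
74,HTN,"ICA, MCA, ACA",306.2,267.07,107.35,209.95,192.48,73.5
48,"HTN, DyL, CAD","ICA, MCA, ACA",194.7,213.98,49.57,124.43,23.34,26.3
54,HTN,"ICA, MCA, ACA",374.72,364.5,351.02,297.75,234.02,65.5
65,"DM, HTN, DyL, CAD","ICA, MCA, ACA",272.4,249.16,123.23,265.25,59.31,56.3
52,"HTN, DM, DyL, CAD, CHF",MCA,288.92,172.52,146.65,197.32,190.42,373.15
69,"HTN, DM, DyL",MCA,390.48,327.67,163.19,242.27,196.09,49
54,"HTN, DyL",MCA,336,372.48,531.1,266.35,235.62,110
82,HTN,"ICA, MCA, ACA",135,163.7,305.96,120.35,56.9,50.5
52,"DM, HTN, DyL","ICA, MCA, ACA",281.11,295.89,309.57,246.23,206.05,81.4
50,"DM, DyL",MCA,406.38,352.34,252.12,274.78,123.86,37
60,"DM, HTN",MCA,321.21,352.98,348.33,387.2,73.91,22
54,HTN,"ICA, MCA, ACA",374.6,359.26,134.17,227.37,173.83,48.3
41,DyL,"ICA, MCA, ACA",437.5,465.99,163.76,396.31,229.25,49.3
67,CHF,MCA,279.22,348.29,386.31,303.61,182.61,49
34,None,MCA,387.53,365.76,181.65,330.65,266.04,73
53,"HTN, DyL",MCA,281.4,313.21,215.17,248.03,124.74,35.3
60,"DM, HTN",MCA,479,268.16,663,236.89,35.04,32.4
35,None,"ICA, MCA, ACA",217.44,266.79,198.55,262.16,132.69,42.36
51,"DM, DyL",MCA,131.8,167.91,84.61,69.47,26.06,32.45
60,"HTN, CAD",MCA,492.34,368.07,284.84,226.06,206.55,125
35,HTN,MCA,326.6,361.09,428.09,287.98,206.48,60.05
61,"DM, HTN, DyL",MCA,220,244.11,68.78,121.23,102.56,53.4
60,HTN,"ICA, MCA, ACA",372.6,318.78,211.04,357.78,146.52,9.35
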