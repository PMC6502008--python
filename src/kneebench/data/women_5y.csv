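klass,label,n_at_risk,failure_pct,diff_pct,ci_low_pct,ci_high_pct,status,p_value
TKR,"MRK cemented, unconstrained fixed",2570,1.35,,,,Reference,
TKR,"AGC cemented, posterior-stabilised fixed",264,2.65,1.31,-0.54,3.16,Non-inferiority not shown,0.083
TKR,"AGC cemented, unconstrained fixed",23829,1.85,0.50,0.13,0.88,Non-inferiority not shown,0.004
TKR,"AGC hybrid, unconstrained fixed",431,3.11,1.76,0.17,3.35,Non-inferiority not shown,0.015
TKR,"AGC uncemented, unconstrained fixed",502,5.34,4.00,2.10,5.89,Inferior by >=100%,<0.001
TKR,"Advance MP cemented, unconstrained fixed",2264,2.46,1.11,0.48,1.75,Inferior by >=20%,<0.001
TKR,"Advance MP Stature cemented, unconstrained fixed",378,2.93,1.58,0.31,2.86,Inferior by >=20%,0.007
TKR,"Advance PS cemented, posterior-stabilised fixed",354,2.97,1.62,0.09,3.15,Non-inferiority not shown,0.019
TKR,"Columbus cemented, unconstrained fixed",1595,2.53,1.19,0.54,1.83,Inferior by >=20%,<0.001
TKR,"E-Motion Bicondylar Knee uncemented, unconstrained mobile",544,3.22,1.87,0.57,3.17,Inferior by >=20%,0.002
TKR,"FS cemented, unconstrained fixed",397,2.34,0.99,-0.48,2.47,Non-inferiority not shown,0.093
TKR,"Genesis 2 cemented, posterior-stabilised fixed",2848,2.15,0.80,0.29,1.32,Inferior by >=20%,0.001
TKR,"Genesis 2 cemented, unconstrained fixed",9021,1.44,0.10,-0.29,0.49,Non-inferiority not shown,0.311
TKR,"Genesis 2 cemented, unconstrained mobile",464,1.48,0.14,-0.94,1.22,Non-inferiority not shown,0.401
TKR,"Genesis 2 Oxinium cemented, posterior-stabilised fixed",620,3.49,2.14,1.00,3.29,Inferior by >=20%,<0.001
TKR,"Genesis 2 Oxinium cemented, unconstrained fixed",1485,2.75,1.41,0.63,2.19,Inferior by >=20%,<0.001
TKR,"Insall-Burstein 2 cemented, posterior-stabilised fixed",1177,2.63,1.28,0.33,2.23,Inferior by >=20%,0.004
TKR,"Journey Oxinium cemented, posterior-stabilised fixed",283,7.30,5.96,3.45,8.47,Inferior by >=100%,<0.001
TKR,"Kinemax cemented, unconstrained fixed",5369,2.41,1.07,0.54,1.59,Inferior by >=20%,<0.001
TKR,"LCS cemented, unconstrained mobile",340,1.85,0.51,-0.90,1.91,Non-inferiority not shown,0.239
TKR,"LCS Complete cemented, unconstrained mobile",3759,2.62,1.28,0.72,1.84,Inferior by >=20%,<0.001
TKR,"LCS Complete uncemented, unconstrained mobile",4205,2.61,1.26,0.73,1.80,Inferior by >=20%,<0.001
TKR,"LCS uncemented, unconstrained mobile",675,2.16,0.82,-0.29,1.92,Non-inferiority not shown,0.073
TKR,"Maxim cemented, posterior-stabilised fixed",282,3.24,1.90,-0.02,3.82,Non-inferiority not shown,0.026
TKR,"Maxim cemented, unconstrained fixed",629,2.34,1.00,-0.16,2.15,Non-inferiority not shown,0.045
TKR,"NRG cemented, posterior-stabilised fixed",1784,2.24,0.90,0.22,1.58,Non-inferiority not shown,0.005
TKR,"NRG cemented, unconstrained fixed",2350,1.79,0.44,-0.11,1.00,Non-inferiority not shown,0.059
TKR,"Natural Knee II cemented, unconstrained fixed",1183,2.34,1.00,0.15,1.84,Non-inferiority not shown,0.010
TKR,"NexGen cemented, posterior-stabilised mobile",414,3.39,2.04,0.49,3.60,Inferior by >=20%,0.005
TKR,"NexGen cemented, posterior-stabilised fixed",16989,2.30,0.95,0.56,1.34,Inferior by >=20%,<0.001
TKR,"NexGen cemented, unconstrained fixed",12603,1.47,0.13,-0.25,0.51,Non-inferiority not shown,0.253
TKR,"NexGen hybrid, unconstrained fixed",454,1.72,0.37,-0.79,1.54,Non-inferiority not shown,0.266
TKR,"NexGen uncemented, posterior-stabilised fixed",514,2.66,1.31,0.10,2.52,Non-inferiority not shown,0.017
TKR,"NexGen uncemented, unconstrained fixed",1421,3.25,1.90,0.98,2.83,Inferior by >=20%,<0.001
TKR,"Optetrak cemented, posterior-stabilised fixed",746,5.29,3.94,2.45,5.44,Inferior by >=100%,<0.001
TKR,"PFC Sigma Bicondylar Knee cemented, posterior-stabilised mobile",2280,2.92,1.57,0.90,2.24,Inferior by >=20%,<0.001
TKR,"PFC Sigma Bicondylar Knee cemented, posterior-stabilised fixed",23690,2.03,0.69,0.31,1.06,Inferior by >=20%,<0.001
TKR,"PFC Sigma Bicondylar Knee cemented, unconstrained fixed",51762,1.61,0.27,-0.09,0.63,Non-inferiority not shown,0.071
TKR,"PFC Sigma Bicondylar Knee cemented, unconstrained mobile",2852,2.72,1.37,0.73,2.01,Inferior by >=20%,<0.001
TKR,"PFC Sigma Bicondylar Knee hybrid, unconstrained fixed",771,1.75,0.40,-0.54,1.34,Non-inferiority not shown,0.202
TKR,"PFC Sigma Bicondylar Knee uncemented, unconstrained mobile",254,1.60,0.25,-1.07,1.57,Non-inferiority not shown,0.355
TKR,"PFC Sigma Bicondylar Knee monobloc polyethylene tibia",1486,1.61,0.27,-0.27,0.80,Non-inferiority not shown,0.163
TKR,"Profix cemented, unconstrained fixed",454,2.58,1.23,-0.19,2.66,Non-inferiority not shown,0.045
TKR,"Profix Oxinium monobloc polyethylene tibia",317,3.58,2.24,0.22,4.26,Non-inferiority not shown,0.015
TKR,"Profix uncemented, unconstrained fixed",1055,1.81,0.47,-0.36,1.29,Non-inferiority not shown,0.134
TKR,"Profix monobloc polyethylene tibia",371,1.47,0.13,-1.09,1.34,Non-inferiority not shown,0.420
TKR,"Rotaglide+ cemented, unconstrained mobile",845,3.08,1.74,0.58,2.89,Inferior by >=20%,0.002
TKR,"Rotaglide cemented, unconstrained mobile",487,2.65,1.31,0.04,2.58,Non-inferiority not shown,0.022
TKR,"Scorpio cemented, posterior-stabilised mobile",662,2.03,0.68,-0.39,1.76,Non-inferiority not shown,0.106
TKR,"Scorpio cemented, posterior-stabilised fixed",3175,2.01,0.67,0.09,1.25,Non-inferiority not shown,0.012
TKR,"Scorpio cemented, unconstrained fixed",5380,2.29,0.94,0.43,1.45,Inferior by >=20%,<0.001
TKR,"Scorpio cemented, unconstrained mobile",601,3.39,2.05,0.61,3.49,Inferior by >=20%,0.003
TKR,"Scorpio hybrid, unconstrained fixed",565,1.95,0.60,-0.54,1.75,Non-inferiority not shown,0.152
TKR,"Scorpio uncemented, unconstrained fixed",1702,2.48,1.14,0.36,1.91,Inferior by >=20%,0.002
TKR,"TC Plus cemented, unconstrained fixed",3820,2.19,0.84,0.28,1.40,Inferior by >=20%,0.002
TKR,"TC Plus cemented, unconstrained mobile",2242,1.52,0.18,-0.41,0.76,Non-inferiority not shown,0.279
TKR,"TC Plus uncemented, unconstrained mobile",712,2.40,1.06,0.02,2.09,Non-inferiority not shown,0.023
TKR,"Triathlon cemented, posterior-stabilised fixed",2754,2.52,1.18,0.63,1.72,Inferior by >=20%,<0.001
TKR,"Triathlon cemented, unconstrained fixed",8378,2.07,0.72,0.32,1.12,Inferior by >=20%,<0.001
TKR,"Triathlon uncemented, unconstrained fixed",257,3.51,2.17,0.50,3.84,Inferior by >=20%,0.005
TKR,"Vanguard cemented, posterior-stabilised fixed",665,2.87,1.53,0.71,2.35,Inferior by >=20%,<0.001
TKR,"Vanguard cemented, unconstrained fixed",4840,1.96,0.61,0.19,1.04,Non-inferiority not shown,0.002
UKR,"AMC/Uniglide Unicondylar, fixed",409,4.80,3.45,1.70,5.21,Inferior by >=100%,<0.001
UKR,"AMC/Uniglide Unicondylar, mobile",479,11.54,10.19,7.69,12.69,Inferior by >=100%,<0.001
UKR,"MG Uni Unicondylar, fixed",953,6.66,5.32,3.77,6.87,Inferior by >=100%,<0.001
UKR,"Oxford Partial Knee Unicondylar, mobile",13555,6.58,5.23,4.74,5.72,Inferior by >=100%,<0.001
UKR,"Physica ZUK Unicondylar, fixed",1113,4.02,2.67,1.80,3.54,Inferior by >=100%,<0.001
UKR,"Preservation Unicondylar, fixed",480,12.12,10.78,8.04,13.52,Inferior by >=100%,<0.001
UKR,"Sigma HP Unicondylar, fixed",688,5.89,4.55,3.35,5.75,Inferior by >=100%,<0.001
UKR,"Sled Unicondylar, fixed",325,8.48,7.13,4.41,9.85,Inferior by >=100%,<0.001
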