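klass,label,n_at_risk,failure_pct,diff_pct,ci_low_pct,ci_high_pct,status,p_value
TKR,"NexGen cemented, unconstrained fixed",8639,1.76,,,,Reference,
TKR,"AGC cemented, unconstrained fixed",16871,2.28,0.52,0.24,0.80,Non-inferiority not shown,<0.001
TKR,"AGC hybrid, unconstrained fixed",369,2.59,0.83,-0.70,2.36,Non-inferiority not shown,0.143
TKR,"AGC uncemented, unconstrained fixed",468,4.87,3.11,1.33,4.88,Inferior by >=20%,<0.001
TKR,"Advance MP cemented, unconstrained fixed",1725,3.18,1.42,0.74,2.11,Inferior by >=20%,<0.001
TKR,"Advance PS cemented, posterior-stabilised fixed",266,3.48,1.72,-0.11,3.55,Non-inferiority not shown,0.033
TKR,"Columbus cemented, unconstrained fixed",1224,2.49,0.73,0.08,1.38,Non-inferiority not shown,0.013
TKR,"E-Motion Bicondylar Knee uncemented, unconstrained mobile",519,2.49,0.73,-0.41,1.88,Non-inferiority not shown,0.105
TKR,"FS cemented, unconstrained fixed",305,1.76,0.00,-1.41,1.40,Non-inferiority not shown,0.497
TKR,"Genesis 2 cemented, posterior-stabilised fixed",1723,2.97,1.21,0.61,1.82,Inferior by >=20%,<0.001
TKR,"Genesis 2 cemented, unconstrained fixed",6545,2.17,0.41,0.08,0.74,Non-inferiority not shown,0.008
TKR,"Genesis 2 cemented, unconstrained mobile",310,3.52,1.76,-0.13,3.65,Non-inferiority not shown,0.034
TKR,"Genesis 2 Oxinium cemented, posterior-stabilised fixed",411,5.27,3.51,1.89,5.13,Inferior by >=100%,<0.001
TKR,"Genesis 2 Oxinium cemented, unconstrained fixed",1175,3.42,1.65,0.76,2.55,Inferior by >=20%,<0.001
TKR,"Insall-Burstein 2 cemented, posterior-stabilised fixed",892,2.88,1.12,0.06,2.17,Non-inferiority not shown,0.019
TKR,"Kinemax cemented, unconstrained fixed",3927,3.08,1.32,0.76,1.87,Inferior by >=20%,<0.001
TKR,"LCS Complete cemented, unconstrained mobile",2774,2.88,1.12,0.54,1.70,Inferior by >=20%,<0.001
TKR,"LCS Complete uncemented, unconstrained mobile",3472,2.36,0.60,0.14,1.06,Non-inferiority not shown,0.005
TKR,"LCS uncemented, unconstrained mobile",485,2.82,1.06,-0.36,2.48,Non-inferiority not shown,0.072
TKR,"MRK cemented, unconstrained fixed",1681,2.07,0.31,-0.26,0.87,Non-inferiority not shown,0.143
TKR,"Maxim cemented, unconstrained fixed",481,1.86,0.10,-1.06,1.25,Non-inferiority not shown,0.436
TKR,"NRG cemented, posterior-stabilised fixed",1291,2.62,0.86,0.10,1.62,Non-inferiority not shown,0.014
TKR,"NRG cemented, unconstrained fixed",1649,3.14,1.38,0.67,2.09,Inferior by >=20%,<0.001
TKR,"Natural Knee II cemented, unconstrained fixed",767,2.02,0.26,-0.65,1.16,Non-inferiority not shown,0.288
TKR,"NexGen cemented, posterior-stabilised mobile",267,3.93,2.17,0.20,4.14,Non-inferiority not shown,0.016
TKR,"NexGen cemented, posterior-stabilised fixed",11354,2.89,1.13,0.81,1.45,Inferior by >=20%,<0.001
TKR,"NexGen hybrid, unconstrained fixed",379,1.47,-0.29,-1.39,0.81,Non-inferiority not shown,0.303
TKR,"NexGen uncemented, posterior-stabilised fixed",568,1.81,0.05,-0.87,0.97,Non-inferiority not shown,0.456
TKR,"NexGen uncemented, unconstrained fixed",1639,3.13,1.36,0.59,2.14,Inferior by >=20%,<0.001
TKR,"Optetrak cemented, posterior-stabilised fixed",533,3.51,1.75,0.29,3.20,Non-inferiority not shown,0.009
TKR,"PFC Sigma Bicondylar Knee cemented, posterior-stabilised mobile",1976,2.65,0.89,0.27,1.51,Non-inferiority not shown,0.002
TKR,"PFC Sigma Bicondylar Knee cemented, posterior-stabilised fixed",15828,2.16,0.40,0.13,0.67,Non-inferiority not shown,0.002
TKR,"PFC Sigma Bicondylar Knee cemented, unconstrained fixed",36856,1.83,0.07,-0.16,0.30,Non-inferior,0.279
TKR,"PFC Sigma Bicondylar Knee cemented, unconstrained mobile",2565,2.75,0.98,0.40,1.57,Inferior by >=20%,0.001
TKR,"PFC Sigma Bicondylar Knee hybrid, unconstrained fixed",619,1.86,0.10,-0.93,1.12,Non-inferiority not shown,0.428
TKR,"PFC Sigma Bicondylar Knee monobloc polyethylene tibia",898,1.69,-0.07,-0.61,0.46,Non-inferiority not shown,0.394
TKR,"Profix cemented, unconstrained fixed",360,3.97,2.21,0.29,4.12,Non-inferiority not shown,0.012
TKR,"Profix uncemented, unconstrained fixed",856,1.21,-0.55,-1.26,0.16,Non-inferior,0.064
TKR,"Rotaglide+ cemented, unconstrained mobile",610,4.40,2.64,1.11,4.17,Inferior by >=20%,<0.001
TKR,"Rotaglide cemented, unconstrained mobile",291,4.30,2.54,0.62,4.45,Inferior by >=20%,0.005
TKR,"Scorpio cemented, posterior-stabilised mobile",517,2.39,0.63,-0.62,1.89,Non-inferiority not shown,0.162
TKR,"Scorpio cemented, posterior-stabilised fixed",2090,2.91,1.14,0.43,1.86,Inferior by >=20%,0.001
TKR,"Scorpio cemented, unconstrained fixed",3667,3.06,1.30,0.75,1.86,Inferior by >=20%,<0.001
TKR,"Scorpio cemented, unconstrained mobile",436,3.94,2.18,0.43,3.93,Inferior by >=20%,0.007
TKR,"Scorpio hybrid, unconstrained fixed",374,3.33,1.57,-0.16,3.30,Non-inferiority not shown,0.038
TKR,"Scorpio uncemented, unconstrained fixed",1440,2.50,0.74,-0.04,1.51,Non-inferiority not shown,0.031
TKR,"TC Plus cemented, unconstrained fixed",3133,3.00,1.23,0.64,1.83,Inferior by >=20%,<0.001
TKR,"TC Plus cemented, unconstrained mobile",1758,2.61,0.84,0.13,1.56,Non-inferiority not shown,0.010
TKR,"TC Plus uncemented, unconstrained mobile",434,1.80,0.04,-1.00,1.07,Non-inferiority not shown,0.473
TKR,"Triathlon cemented, posterior-stabilised fixed",1851,2.53,0.77,0.23,1.31,Non-inferiority not shown,0.003
TKR,"Triathlon cemented, unconstrained fixed",5995,1.94,0.18,-0.13,0.48,Non-inferiority not shown,0.126
TKR,"Vanguard cemented, posterior-stabilised fixed",471,2.57,0.81,-0.05,1.67,Non-inferiority not shown,0.033
TKR,"Vanguard cemented, unconstrained fixed",3489,2.10,0.34,-0.01,0.70,Non-inferiority not shown,0.028
UKR,"AMC/Uniglide Unicondylar, fixed",348,3.97,2.21,0.51,3.90,Inferior by >=20%,0.005
UKR,"AMC/Uniglide Unicondylar, mobile",519,8.90,7.14,5.06,9.22,Inferior by >=100%,<0.001
UKR,"MG Uni Unicondylar, fixed",1130,5.36,3.60,2.33,4.86,Inferior by >=100%,<0.001
UKR,"Oxford Partial Knee Unicondylar, mobile",14581,5.72,3.96,3.59,4.33,Inferior by >=100%,<0.001
UKR,"Physica ZUK Unicondylar, fixed",1280,3.88,2.12,1.35,2.89,Inferior by >=20%,<0.001
UKR,"Preservation Unicondylar, fixed",566,8.55,6.79,4.61,8.96,Inferior by >=100%,<0.001
UKR,"Sigma HP Unicondylar, fixed",948,4.36,2.59,1.75,3.44,Inferior by >=20%,<0.001
UKR,"Sled Unicondylar, fixed",261,11.47,9.71,6.30,13.12,Inferior by >=100%,<0.001
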