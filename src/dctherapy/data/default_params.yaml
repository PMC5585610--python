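r_T: 0.002
a_T: 0.1136
K_T: 1000000000000.0
e_T: 50.0
a_H: 0.0001
r_H: 1.0
K_H: 1.0
mu_H: 0.005
a_C: 0.0001
r_C: 4.0e-07
K_C: 1.0
mu_C: 0.005
mu_D: 0.009625
r_I: 0.01
mu_IC: 1.0e-07
mu_I: 0.01
r_Tbeta: 5.57e-06
mu_beta: 6.93
a_Tbeta: 0.69
e_Tbeta: 10000.0
a_gammaC: 0.000102
mu_gamma: 0.102
g_Ml: 1.44
a_Mlgamma: 2.89
e_Mlgamma: 338000.0
mu_Ml: 0.0144
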