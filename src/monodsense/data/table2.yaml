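# Published parameter set of the macroscopic Monod model for CHO
# fed-batch culture.  Units: mu_max, k_d in 1/h; K_* in mM; Y_X_* in
# 1e9 cells/mmol; Y_lac_glc, Y_amm_gln in mmol/mmol; r_amm, m_glc, a1
# in 1e-12 mmol/cell/h; a2 in mM; Q_mAb in 1e-12 g/cell/h.
mu_max: 0.039
k_d: 0.004
K_glc: 1.00
K_gln: 0.047
K_Ilac: 43.00
K_Iamm: 6.51
K_Dlac: 45.8
K_Damm: 6.51
Y_X_glc: 0.357
Y_X_gln: 0.974
Y_lac_glc: 0.70
Y_amm_gln: 0.67
r_amm: 6.3
m_glc: 69.2
a1: 3.2
a2: 2.1
Q_mAb: 1.51
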