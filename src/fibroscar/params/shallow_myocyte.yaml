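# TP06 human ventricular myocyte, epicardial, Shallow-restitution set
# (maximum S1S2 restitution slope ~0.7).  Conductances in nS/pF unless
# the source formulation uses other units; Cm in pF.
schema_version: 1
kind: myocyte_params
params:
  g_na: 14.838
  g_to: 0.294
  g_k1: 5.405
  g_kr: 0.172
  g_ks: 0.441
  g_cal: 3.980e-05
  k_naca: 1000.0
  k_nak: 2.724
  g_pca: 0.8666
  g_pk: 0.00219
  g_bca: 0.000592
  g_bna: 0.00029
  cm_pF: 150.0
  variant: Shallow
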