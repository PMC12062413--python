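# MacCannell active fibroblast, hyperpolarized variant: the Kv
# gating-voltage shift is calibrated so the uncoupled unit rests at
# -49.0 mV.  Conductances in nS/pF, capacitance per fibroblast in pF.
schema_version: 1
kind: fibroblast_params
params:
  g_fk1: 0.4822
  g_fkv: 0.25
  i_fnak_max: 2.002
  g_fbna: 0.0095
  cf_pF: 50.0
  nf: 8
  kv_shift_mV: -0.098522
  variant: hyperpolarized
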