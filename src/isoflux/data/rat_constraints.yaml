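intake: 10.0
diet_delta: 3.5
fsr:
  SIp: 1.5
  Lp: 0.5
  Plp: 0.25
  Mp: 0.11
  Kp: 0.42
  Hp: 0.2
  Rp: 0.03
  Skp: 0.07
ti:
  M: 1.5
  K: 1.5
  H: 1.5
  R: 1.5
  Sk: 0.8
secretion_frac_intake: 0.5
ileal_digestibility: 0.9
fecal_frac_intake: 0.099
ammonia_frac_intake: 0.051
hair_loss_frac_intake: 0.02
desquamation_frac_intake: 0.01
delivery_frac_intake: 2.5
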