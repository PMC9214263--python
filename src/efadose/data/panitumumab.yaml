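# Panitumumab vs. EGFR in colorectal cancer: 2-compartment anti-receptor model.
# EGFR amounts are bottom-up calculations over expressing tissues.
name: panitumumab
drug:
  name: panitumumab
  modality: anti_receptor
  arms:
    - target: egfr
      kd: 0.05          # nM
      valency: 2
  half_life: 16 d
  mw: 150000.0          # typical mAb MW
targets:
  egfr:
    kind: membrane_receptor
    amount_central: 4.57e-2     # nmol
    amount_peripheral: 14.7     # nmol
    receptor_half_life: 5       # h
physiology:
  volume_central: 3.0           # L, plasma
  volume_peripheral: 13.0       # L, peripheral interstitial
  body_weight: 70.0
  pdist: 0.19                   # typical antibody biodistribution coefficient
  tdist: 35                     # h
regimen:
  route: IV
  dose_mg_per_kg: 6.0           # approved dose, Q2W
  interval: 2 weeks
  to_steady_state: true
criterion:
  metric: TE
  threshold: 98.0
  compartment: peripheral
  evaluation: steady_state
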