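# Emibetuzumab (LY2875358) vs. c-Met: 2-compartment anti-receptor model with
# a shed soluble receptor acting as a decoy sink.
name: emibetuzumab
drug:
  name: emibetuzumab
  modality: anti_receptor
  arms:
    - target: cmet
      kd: 0.1           # nM
      valency: 2
  half_life: 16 d
  mw: 150000.0
targets:
  cmet:
    kind: membrane_receptor
    amount_central: 3.20e-2     # nmol
    amount_peripheral: 5.86     # nmol
    receptor_half_life: 4       # h
    shed:
      soluble_baseline_central: 5.9   # nM plasma soluble Met
      soluble_half_life: 48           # h
physiology:
  volume_central: 3.0
  volume_peripheral: 13.0
  body_weight: 70.0
  pdist: 0.19
  tdist: 35
regimen:
  route: IV
  dose_mg: 210.0                # dose level with saturating soluble-Met response
  interval: 2 weeks
  to_steady_state: true
criterion:
  metric: TE
  threshold: 98.0
  compartment: peripheral
  evaluation: steady_state
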