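# Amivantamab: EGFR x c-Met bispecific, 2-compartment model.  One binding arm
# per target (no avidity); c-Met has an elevated shed soluble form.
name: amivantamab
drug:
  name: amivantamab
  modality: bispecific_receptor
  arms:
    - target: egfr
      kd: 1.4           # nM
      valency: 1
    - target: cmet
      kd: 0.04          # nM
      valency: 1
  half_life: 11 d
  mw: 150000.0
targets:
  egfr:
    kind: membrane_receptor
    amount_central: 4.57e-2
    amount_peripheral: 14.7
    receptor_half_life: 5
  cmet:
    kind: membrane_receptor
    amount_central: 3.20e-2
    amount_peripheral: 5.86
    receptor_half_life: 4
    shed:
      soluble_baseline_central: 5.9
      soluble_half_life: 48
physiology:
  volume_central: 3.0
  volume_peripheral: 13.0
  body_weight: 70.0
  pdist: 0.19
  tdist: 35
regimen:
  route: IV
  dose_mg: 1050.0               # approved maintenance dose, Q2W
  interval: 2 weeks
  to_steady_state: true
criterion:
  metric: TE
  threshold: 98.0
  compartment: peripheral
  evaluation: steady_state
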