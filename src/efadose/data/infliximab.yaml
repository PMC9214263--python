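# Infliximab vs. TNFa in rheumatoid arthritis: 1-compartment anti-ligand model.
# Maintenance regimen only (the week-0/2/6 loading phase is not modelled).
name: infliximab
drug:
  name: infliximab
  modality: anti_ligand
  arms:
    - target: tnfa
      kd: 0.0042        # nM (4.2 pM, Kinexa)
      valency: 1
  half_life: 14 d
  mw: 149100.0
targets:
  tnfa:
    kind: soluble_ligand
    baseline_conc: 5.73e-5
    half_life: 30 min
    receptor_kd: 0.019
    receptor_total: 0.23
    receptor_half_life: 9
physiology:
  volume_central: 5.0
  volume_peripheral: 0.0
  body_weight: 70.0
regimen:
  route: IV
  dose_mg_per_kg: 3.0           # approved maintenance dose, Q8W
  interval: 8 weeks
  n_doses: 7
criterion:
  metric: ID
  threshold: 90.0
  evaluation: n_doses
  n_doses: 7
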