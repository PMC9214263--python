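# Adalimumab vs. TNFa in rheumatoid arthritis: 1-compartment anti-ligand model.
# Literature parameters; durations accept explicit units and are converted to
# hours on ingestion.
name: adalimumab
drug:
  name: adalimumab
  modality: anti_ligand
  arms:
    - target: tnfa
      kd: 0.0086        # nM (8.6 pM, Kinexa)
      valency: 1        # effective valency vs. the TNFa homotrimer
  half_life: 20 d
  mw: 148000.0
  absorption_half_life: 2.5 d   # typical antibody SC absorption
  bioavailability: 1.0
targets:
  tnfa:
    kind: soluble_ligand
    baseline_conc: 5.73e-5      # nM, plasma TNFa in RA patients
    half_life: 30 min
    receptor_kd: 0.019          # nM, TNFa:TNFR
    receptor_total: 0.23        # nM, bottom-up TNFR1
    receptor_half_life: 9       # h
physiology:
  volume_central: 5.0           # L, typical mAb volume of distribution
  volume_peripheral: 0.0
  body_weight: 70.0
regimen:
  route: SC
  dose_mg: 40.0                 # approved initial dose, Q2W
  interval: 2 weeks
  n_doses: 7
criterion:
  metric: ID
  threshold: 90.0
  evaluation: n_doses
  n_doses: 7
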