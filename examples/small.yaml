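# Small end-to-end run: 2 plates x 12 wells, one 384 px field per well.
seed: 0
cells_per_well: 40

layout:
  n_plates: 2
  wells_per_plate: 12
  fields_per_well: 1
  conditions: [DMSO, TLR8]
  timepoints: [24.0]
  donors: [d01, d02]
  cohorts: {d01: HV, d02: PLWH}

render:
  field_px: 384

effects:
  donor_sd: 0.15
  effects:
    - {condition: TLR8, timepoint_h: 24.0, contracted_fold: 1.55,
       annexin_fold: 1.8}

classifier:
  families: [size, annexin, fragment, actin]
  n_estimators: 100

cytokines:
  enabled: true
  donor_sd: 0.3
  noise_sd: 0.2
  fold_effects:
    "TLR8|24.0|IL-6": 4.0
    "TLR8|24.0|TNF-a": 3.0
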