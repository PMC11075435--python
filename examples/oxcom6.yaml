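# Six-strain community demo: two pea root samples, simulated background,
# background subtraction enabled.  Run with:
#   dfmflow run --config examples/oxcom6.yaml --out results/oxcom6
seed: 3841
simulate:
  strains:
    OpAA2: R
    AoDQS-4: Y
    PfSBW25: B
    EcAA4: RY
    Rlv3841: RB
    AxAT1: YB
samples:
  - sample_id: pea_7dpi_rep1
    plant: pea
    timepoint: 7.0
    replicate: 1
    n_events: 12000
    root_mass_g: 0.5
    acquisition_time_min: 10.0
  - sample_id: pea_7dpi_rep2
    plant: pea
    timepoint: 7.0
    replicate: 2
    n_events: 12000
    root_mass_g: 0.5
    acquisition_time_min: 10.0
background:
  n_events: 5000
  replicates: 3
  root_mass_g: 0.5
  acquisition_time_min: 10.0
subtract_background: true
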