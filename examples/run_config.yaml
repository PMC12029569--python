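# End-to-end synthetic run for `g4probe all`.
# All inputs are generated from these ground-truth parameters with the
# given seed; reports land under <out>/reports/.
seed: 20250929

# Synthetic stand-in probe sequence (telomere-derived 22-mer) used for CF
# annotation; replace with the real assay probe for real data.
probe_sequence: AGGGTTAGGGTTAGGGTTAGGG

sequences:
  n_decoys: 3

fretmc:
  # condition -> true Tm (deg C); strong competitors pull the
  # ligand-stabilized Tm back toward the probe-alone value
  tm_by_condition:
    F21T: 44.0
    "F21T+PhenDC3": 61.0
    AT14: 46.0        # strong G4 competitor: S near 0
    AT14T: 57.0       # weaker competitor: S nearer 1
  dt: 3.0
  noise_sd: 0.005

isofret:
  f_by_competitor:
    AT14: 0.15        # G4 former: ligand sequestered, duplex forms, low F
    AT14T: 0.25
    decoy1: 0.95      # inert oligo: F near 1
  noise_rel: 0.02

spectra:
  dilution_factor: 1.05

titration:
  kd_molar: 4.6e-9
  n_hill: 1.5
  probe_conc: 100.0e-9
  noise_rel: 0.01
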