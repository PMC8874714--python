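# Default analysis profile for the CYP102A1 (P450 BM3) electron-transfer
# study.  Every constant the pipeline uses lives here, not in code.
calibration:
  # two (distance Å, rate s^-1) anchors spanning the 5-15 Å range where
  # inter-center protein ET rates of 1e10-1e5 s^-1 are observed
  points:
    - {distance: 5.0, rate: 1.0e+10}
    - {distance: 15.0, rate: 2.5e+5}
  # independent consistency anchor (homodimer limiting step); verified, not fitted
  anchor: {distance: 30.0, rate: 0.03}
  anchor_tolerance_factor: 1.2

domains:
  # author-numbered residue ranges of the three globular domains
  ranges:
    HEME: [2, 459]
    FMN: [460, 650]
    FAD: [659, 1049]
  residue_codes: {HEM: HEM, FMN: FMN, FAD: FAD}

equilibrium:
  kd: 1.1e-9            # dimer dissociation constant, M
  concentrations: [1.0e-7, 5.0e-7]   # assay total concentrations, M

pathway:
  # experimental indole-hydroxylation turnover numbers per enzyme form, s^-1
  kcat: {wt: 0.03, a83i: 0.19, a83f: 6.0}
  consistency_bounds: [0.3333333333333333, 3.0]
  aromatic_contact_threshold: 4.0    # Å, flags ring-to-heme relay contacts
  cross_rejection_rate: 1.0e-7       # s^-1, below which a cross route is rejected
  aromatic_residues: [262]           # candidate relay residues (chain A numbering)

seed: 0
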