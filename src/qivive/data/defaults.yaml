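# Default run configuration: two model estrogens (17beta-estradiol and
# bisphenol A), male/female rat liver S9 clearance variants, the standard
# rat physiology, and the oral scenarios used for model evaluation.
#
# Chemical parameter provenance: log Pow and Caco-2 Papp from the published
# literature; CLint (uL/min/mg S9 protein) and fractions unbound from
# substrate-depletion and rapid-equilibrium-dialysis measurements.

seed: 20170
output_dir: results

solver:
  method: LSODA
  rtol: 1.0e-8
  atol: 1.0e-12

physiology: {}   # empty: use the built-in adult-rat defaults

chemicals:
  e2_male:
    mw: 272.38
    log_pow: 4.01
    papp_caco2: 17.0
    clint_invitro: 175.0
    fub_serum: 0.050
    fub_medium: {yes_assay: 1.0, er_calux: 0.628, mcf7_bos: 0.628}
  e2_female:
    mw: 272.38
    log_pow: 4.01
    papp_caco2: 17.0
    clint_invitro: 65.5
    fub_serum: 0.050
    fub_medium: {yes_assay: 1.0, er_calux: 0.628, mcf7_bos: 0.628}
  bpa_male:
    mw: 228.29
    log_pow: 3.32
    papp_caco2: 20.0
    clint_invitro: 392.0
    fub_serum: 0.040
    fub_medium: {yes_assay: 1.0, er_calux: 0.461, mcf7_bos: 0.461}
  bpa_female:
    mw: 228.29
    log_pow: 3.32
    papp_caco2: 20.0
    clint_invitro: 431.6
    fub_serum: 0.040
    fub_medium: {yes_assay: 1.0, er_calux: 0.461, mcf7_bos: 0.461}

scenarios:
  - {chemical: e2_male, route: oral, dose_mg_per_kg: 0.02, duration_h: 24.0}
  - {chemical: e2_male, route: oral, dose_mg_per_kg: 0.08, duration_h: 24.0}
  - {chemical: bpa_male, route: oral, dose_mg_per_kg: 10.0, duration_h: 24.0}
  - {chemical: bpa_male, route: oral, dose_mg_per_kg: 100.0, duration_h: 24.0}

# Synthetic-fixture settings for the demo pipeline: yeast-screen-like
# potencies (the least sensitive but best-extrapolating assay family) and
# uterotrophic designs typical for a strong (E2-like) and weak (BPA-like)
# estrogen.
fixtures:
  hill:
    e2_male: {assay: yes_assay, ec50_m: 1.0e-9, slope: 1.0}
    bpa_male: {assay: yes_assay, ec50_m: 1.0e-5, slope: 1.0}
  uterotrophic:
    e2_male: {a: 100.0, b: 2.5, d: 1.0, doses: [0.0, 0.01, 0.02, 0.04, 0.1, 0.2, 0.4]}
    bpa_male: {a: 100.0, b: 0.0004, d: 1.0, doses: [0.0, 10.0, 100.0, 300.0, 600.0, 800.0]}
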