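# Parameter presets matching the published experimental conditions for
# doxorubicin (DOX) and its tetrapeptide conjugate (4-pep-DOX) binding to
# a 20-bp dsDNA duplex in 10 mM Tris-HCl, pH 7.2, 25 degC.
# All synthetic fixtures in tests and the CLI `simulate` command are
# generated from these values.

uvvis:
  eps_f_per_M_cm: 11500.0        # free-chromophore extinction at 480 nm
  eps_b_per_M_cm: 6000.0         # bound (hypochromic) extinction, synthetic choice
  ligand_total_M: 1.8e-5
  dna_max_M: 1.9e-6
  n_points: 10
  ligands:
    DOX:       {K_A_per_M: 1.10e6}
    4-pep-DOX: {K_A_per_M: 0.54e6}

fluorescence:
  F0_au: 1000.0
  q_min_M: 5.0e-9
  q_max_M: 7.5e-8
  n_points: 15
  ligands:
    DOX:       {K_A_per_M: 1.10e7, tau0_ns: 1.057}
    4-pep-DOX: {K_A_per_M: 0.56e7, tau0_ns: 1.076}

lifetime:
  n_channels: 256
  channel_width_ns: 0.05
  total_counts: 1.0e6
  ligands:
    DOX:       {tau_ns: 1.057}
    4-pep-DOX: {tau_ns: 1.076}

itc:
  cell_volume_mL: 1.400
  ligands:
    DOX:
      n_sites: 7.29
      logK: 6.03
      dH_kcal_mol: -9.52
      syringe_conc_mM: 0.174
      cell_conc_mM: 0.002
    4-pep-DOX:
      n_sites: 7.98
      logK: 4.24
      dH_kcal_mol: -5.84
      syringe_conc_mM: 0.470
      cell_conc_mM: 0.005
  injection_volumes_uL: first_2uL_then_28x10.02uL
  noise_fraction_of_max: 0.01

pmf:
  windows:
    n: 21
    first_center_nm: 0.2
    spacing_nm: 0.2
    force_const_kcal_mol_nm2: 143.05
  kT_kcal_mol: 0.5925
  n_samples_per_window: 10000
  profiles:
    # Intercalation free-energy profiles versus the site-chromophore
    # separation r: a deep intercalated well near 0.2 nm, a surface-bound
    # shoulder near 1.1 nm, and a dissociated plateau defining zero.
    dox_minor:
      plateau_start_nm: 2.6
      control_points:
        - [0.10,  6.0]
        - [0.15, -4.0]
        - [0.20, -9.8]
        - [0.30, -8.6]
        - [0.45, -5.5]
        - [0.60, -3.0]
        - [0.75, -2.2]
        - [0.90, -3.6]
        - [1.10, -4.5]
        - [1.30, -3.8]
        - [1.60, -2.2]
        - [1.90, -1.1]
        - [2.20, -0.4]
        - [2.60,  0.0]
        - [3.00,  0.0]
        - [3.40,  0.0]
        - [3.80,  0.0]
        - [4.40,  0.0]
    dox_major:
      plateau_start_nm: 2.6
      control_points:
        - [0.10,  8.0]
        - [0.20, -2.3]
        - [0.35, -1.5]
        - [0.55, -0.2]
        - [0.80, -1.2]
        - [1.10, -1.8]
        - [1.50, -1.0]
        - [1.90, -0.4]
        - [2.30, -0.1]
        - [2.60,  0.0]
        - [3.20,  0.0]
        - [4.40,  0.0]
    pep_major:
      plateau_start_nm: 2.6
      control_points:
        - [0.10,  8.0]
        - [0.20, -4.5]
        - [0.35, -3.6]
        - [0.55, -1.5]
        - [0.80, -2.0]
        - [1.10, -2.6]
        - [1.50, -1.5]
        - [1.90, -0.6]
        - [2.30, -0.1]
        - [2.60,  0.0]
        - [3.20,  0.0]
        - [4.40,  0.0]
    pep_minor:
      plateau_start_nm: 2.6
      control_points:
        - [0.10,  9.0]
        - [0.20, -0.8]
        - [0.40, -0.3]
        - [0.70, -1.0]
        - [1.10, -1.4]
        - [1.50, -0.8]
        - [1.90, -0.3]
        - [2.30, -0.05]
        - [2.60,  0.0]
        - [3.20,  0.0]
        - [4.40,  0.0]

cluster:
  cutoff_nm: 0.3
  population_presets:
    dox_minor:  [0.85, 0.15]
    pep_major:  [0.74, 0.26]
  jitter_sd_nm: 0.02
  inter_center_rmsd_nm: 1.0
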