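# Shipped default configuration: six gluten marker peptides, their heavy
# internal standard, the published transition list as printed (including its
# known misprints -- run `glutenprm transitions validate` to see them), the
# chromatography gradient and instrument parameters.
#
# Fragment entries with `assigned: false` are stored as opaque m/z values:
# the printed label matches no recomputable backbone ion, so they are kept
# verbatim and flagged by the validator rather than silently corrected.

seed: 0

peptides:
  - name: P1
    sequence: LQLQPFPQPQLPY
    charges: [2]
    rt_min: 6.11
  - name: P1H
    sequence: LQLQPFPQPQLPY
    charges: [2]
    rt_min: 6.11
    # Nominal label: 13C9,15N phenylalanine at residue six (+10.027 Da by
    # composition).  The printed heavy transition list implies +6.000 Da;
    # the override keeps the shipped list faithful to print and the
    # validator reports the disagreement.
    label: {position: 6, c13: 9, n15: 1, delta_da: 5.99960}
  - name: P2
    sequence: LQLQPFPQPQLPYPQPQPF
    charges: [3]
    rt_min: 6.59
  - name: P3
    sequence: LQLQPFPQPQLPYPQPHLPYPQPQPF
    charges: [3]
    rt_min: 7.12
  - name: P4
    sequence: LQLQPFPQPQLPYPQPQLPYPQPQPF
    charges: [3]
    rt_min: 6.43
  - name: P5
    sequence: LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF
    charges: [4]
    rt_min: 7.29
  - name: P6
    sequence: RPQQPYPQPQPQY
    charges: [2]
    rt_min: 3.48

# 9-mer HLA-DQ2.5 epitope cores, native (non-deamidated) sequences from the
# standard celiac epitope registry nomenclature (Sollid et al.).  Editable:
# the cores are not part of the transition list and only drive motif counts.
# Note P6 (RPQQPYPQPQPQY) carries residues 2-9 of the a3 core but lacks its
# leading F, so the a3 count on P6 is 0 with this registry core.
epitopes:
  - {name: DQ2.5-glia-a1a, core: PFPQPQLPY}
  - {name: DQ2.5-glia-a1b, core: PYPQPQLPY}
  - {name: DQ2.5-glia-a2, core: PQPQLPYPQ}
  - {name: DQ2.5-glia-a3, core: FRPQQPYPQ}

# Transition list exactly as printed in the source method (m/z in Th,
# retention times in minutes).  Known misprints are retained on purpose.
transitions:
  - peptide: P1
    precursor_mz: 784.927
    charge: 2
    rt_min: 6.11
    fragments:
      - {label: y2, mz: 279.134}
      - {label: b4, mz: 483.293}
      - {label: b6, mz: 470.240, assigned: false}
      - {label: b11, mz: 1290.719}
  - peptide: P1H
    precursor_mz: 787.927
    charge: 2
    rt_min: 6.11
    fragments:
      - {label: y2, mz: 279.134}
      - {label: b4, mz: 483.293}
      - {label: "b6*", mz: 476.254}
      - {label: b11, mz: 1296.731}
  - peptide: P2
    precursor_mz: 755.068
    charge: 3
    rt_min: 6.59
    fragments:
      - {label: y4, mz: 488.251}
      - {label: b8, mz: 952.526}
      - {label: b9, mz: 1049.544}
  - peptide: P3
    precursor_mz: 1029.543
    charge: 3
    rt_min: 7.12
    fragments:
      - {label: y2, mz: 263.139}
      - {label: b7, mz: 824.429}
      - {label: y6, mz: 713.357}
      - {label: b8, mz: 952.527}
      - {label: b11, mz: 1290.722}
  - peptide: P4
    precursor_mz: 1032.543
    charge: 3
    rt_min: 6.43
    fragments:
      - {label: y2, mz: 263.139}
      - {label: y4, mz: 488.250}
      - {label: y6, mz: 713.358}
      - {label: y8, mz: 973.479}
  - peptide: P5
    precursor_mz: 978.264
    charge: 4
    rt_min: 7.29
    fragments:
      - {label: y4, mz: 488.252}
      - {label: b21, mz: 824.429}
      - {label: y8, mz: 973.480}
      - {label: b11, mz: 1290.726}
  - peptide: P6
    precursor_mz: 813.905
    charge: 2
    rt_min: 3.48
    fragments:
      - {label: y3, mz: 407.194}
      - {label: a8, mz: 967.513}
      - {label: b9, mz: 995.508}

acquisition:
  # (time min, %B, flow mL/min); run starts equilibrated at 3 %B.
  gradient:
    - [0.00, 3, 0.30]
    - [1.00, 7, 0.30]
    - [3.00, 25, 0.30]
    - [3.90, 40, 0.30]
    - [8.00, 95, 0.40]
    - [9.50, 95, 0.40]
    - [12.00, 95, 0.30]
    - [12.50, 7, 0.30]
    - [15.07, 7, 0.30]
  instrument:
    spray_voltage: "35 kV"
    spray_current: "17 uA"
    aux_gas_flow_rate: "10"
    sheath_gas_flow_rate: "45"
    scan_range: "108-4015 m/z"
    resolving_power: "70,000"
    capillary_temperature: "320 C"
    normalised_collision_energy: "Stepped 18-27"
    mobile_phase_a: "99.9% water, 0.1% formic acid"
    mobile_phase_b: "99.9% ACN, 0.1% formic acid"
    column_temperature: "40 C"
    injection_volume: "2 uL"

quant:
  match_tolerance_th: 0.01
  precursor_tol_th: 0.005
  fragment_tol_th: 0.015
  dilution_factor: 2.1       # SPE: 200 uL loaded, 2 x 210 uL eluted
  blank_k: 10
  window_halfwidth_min: 0.5
  weighting: null
  calibration_levels: [0.5, 1, 2, 5, 10]
  lodloq_levels: [10, 5, 2, 1, 0.5, 0.3, 0.1, 0.05, 0.03, 0.01]
  lodloq_injections: 5
  internal_standard: P1H
  spike_concentration: 3.0   # ug/mL

simulation:
  sigma_min: 0.05
  noise_sd: 0.0
  baseline: 0.0
  dt_min: 0.005
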