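# glutenprm

A toolkit for targeted parallel-reaction-monitoring (PRM) label-free
quantification of six immunogenic gluten marker peptides (P1–P6, plus the
isotope-labelled internal standard P1H), covering the full desk side of the
workflow:

- **`glutenprm.chem`** — monoisotopic/average peptide masses, precursor and
  b/y/a fragment-ion m/z (with single-residue stable-isotope labels),
  proline content, and overlapping epitope-motif counting.
- **`glutenprm.transitions`** — PRM inclusion-list construction from
  sequences, in-silico/observed spectrum matching, top-k fragment selection,
  scheduled retention windows, CSV export/import, and a validator that
  cross-checks a printed transition list against first-principles
  recomputation (reporting discrepancies instead of silently fixing them).
- **`glutenprm.digestion`** — static three-phase in vitro digestion
  planning: simulated-fluid recipes from 1.25× stocks, per-phase volume
  schedule (with gastric sampling-loss accounting), enzyme dosing by
  activity, and TFA quench volumes.
- **`glutenprm.simulate`** — seeded synthetic extracted-ion chromatograms
  with known ground truth: calibration series, low-level dilution series
  for LOD/LOQ, matrix-suppression scenarios, and day-to-day variation.
- **`glutenprm.quantify`** — trapezoidal XIC integration, OLS external
  calibration, residual-sd LOD/LOQ (3.3·S/slope and 10·S/slope, plus a
  blank-based mean + k·sd rule), back-calculation with dilution-factor and
  internal-standard-recovery correction, matrix-effect and CV reports.
- **`glutenprm.config`** — YAML configuration (a shipped default reproduces
  the published peptides, transition list, gradient, instrument parameters
  and fluids), validation, and the end-to-end pipeline with a reproducible
  run log (seed + config hash).

## Command line

A single umbrella command `glutenprm` (exit codes: 0 ok, 1 validation
error, 2 runtime error). Global options `--config`, `--seed`,
`--log-level` come before the subcommand.

```sh
# recompute + schedule the inclusion list, and audit the shipped one
glutenprm transitions build --out inclusion.csv
glutenprm transitions validate

# bench sheet for 1.25 g of freeze-dried sample with one 1 mL gastric aliquot
glutenprm digestion plan --mass 1.25 --aliquot 1.0 --fluid-volumes

# simulate a calibration bundle, then quantify it
glutenprm --seed 5 simulate --out-dir sim --mode calibration --replicates 3
glutenprm quantify --chromatograms sim/chromatograms.csv \
    --calibration calibration.csv --unknowns unknowns.csv --out-dir out

# detection limits from a low-level dilution series
glutenprm lodloq --chromatograms sim/chromatograms.csv --calibration cal.csv

# matrix-effect and day-to-day replicability summaries
glutenprm matrix-effect --abundances abundances.csv
glutenprm replicability --values days.csv
```

Chromatograms are exchanged as long-format CSV
(`sample_id, transition_id, time_min, intensity`); calibration manifests as
`sample_id, peptide, level`; unknowns as `sample_id, peptide`
(optionally `dilution_factor`, `recovery`).

## Notes on the shipped transition list

The default configuration stores the published transition list **as
printed**, including its internal inconsistencies. `glutenprm transitions
validate` reports exactly: the transposed P3/P4 precursor pair; the P1H
label override (+6.000 Da, implied by the printed heavy precursor) versus
its nominal 13C9,15N composition (+10.027 Da); two unassignable "b6"
fragments (P1/P1H); and three fragment m/z that match no backbone ion of
the printed ordinal (P2 b9, P3 b7, P6 b9 — the last being the computed b8).
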