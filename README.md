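# ramanauth

Chemometric authentication of PDO grated cheese from handheld Raman
spectra. The package implements the full analysis chain used to (i)
decide whether a grated-cheese package comes from the authentic target
product (one-class SIMCA class modeling) and (ii) estimate its rind
content in % w/w and check compliance with the 18 % limit (PLS
regression). Because no real spectra are distributed, a synthetic
generator produces Raman-like two-session campaigns with the same
statistical structure, so every stage is testable offline.

## Components

| module | what it does |
|---|---|
| `ramanauth.synthetic` | Raman-like spectrum generator: pulp/rind linear mixtures, competitor class, constant packaging contribution, fluorescence baseline, noise, per-session shift/gain, 5 point spectra per package, replicate acquisitions |
| `ramanauth.preprocess` | fixed-order chain: point averaging → Savitzky-Golay (21, 2) → correlation optimized warping → weighted-least-squares baseline → unit-area or PQN normalization |
| `ramanauth.simca` | alternative-SIMCA (reduced-distance rule, accept iff √((Q/Q_lim)² + (T²/T²_lim)²) ≤ √2), DDSIMCA, ROC-driven selection, venetian-blind CV, complexity criteria, sensitivity/specificity/efficiency |
| `ramanauth.pls` | NIPALS PLS1, RMSECV latent-variable selection (random subsets), VIP scores, duplex calibration updating, 18 % compliance classification |
| `ramanauth.selection` | classic duplex representative subset selection on PC scores |
| `ramanauth.pipeline` / `ramanauth.cli` | end-to-end authenticity and rind workflows from a single YAML config |

## CLI

Each command takes `--config <yaml>`, `--out <dir>`, `--seed <int>`;
without a config the default synthetic campaign is used. Exit codes:
0 ok, 2 config error, 3 data error.

```sh
# generate a synthetic campaign (spectra.csv / metadata.csv / truth.csv)
ramanauth simulate --out runs/sim --seed 1

# one-class authenticity workflow (Table-2-style report)
ramanauth authenticity --out runs/auth --seed 1

# rind-content calibration with duplex update (Table-3-style report)
ramanauth rind --out runs/rind --seed 1
```

A config file may point at existing CSVs instead of the generator:

```yaml
paths:
  spectra: runs/sim/spectra.csv
  metadata: runs/sim/metadata.csv
preprocess:
  sg_window: 21
  cow_segment: 50
  cow_slack: 10
simca:
  alpha: 0.05
  a_max: 6
pls:
  max_lv: 10
  threshold: 18.0
  update_k: 6
```

The spectra CSV is wide format (first column `spectrum_id`, remaining
header row the numeric wavenumber grid, 400–2300 cm⁻¹); the metadata CSV
carries `spectrum_id, package_id, class, rind_pct, session,
replicate_group, point_index, role`.

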