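# cytosim

Agent-based simulation of cytoneme-mediated morphogen (Wnt) transport on a
growing epithelial tissue wrapped around a circular yolk, with fate
thresholding and boundary estimation.

The model couples:

- **tissue mechanics** — cell-centre off-lattice dynamics with linear springs
  between Delaunay neighbours, an outward yolk-surface force, an inward
  intercalation force, and overdamped explicit Euler integration
  (`cytosim.mechanics`);
- **population dynamics** — receiver-cell division as a renewal process with
  uniformly drawn clocks, and Poisson apoptosis (`cytosim.population`);
- **cytoneme transport** — per source cell, a Poisson number of straight
  filopodia that grow by positive-truncated normal increments along a
  tangent-biased direction, retract stochastically (or on exceeding a maximum
  length, or on an empty tip) and are instantaneously replaced so the global
  count is conserved; tips in contact with a receiver probabilistically
  deposit a fixed fraction of their initial ligand load; receiver ligand
  decays exponentially (`cytosim.cytonemes`);
- **analysis** — fate calling against a threshold, angular binning of
  hindbrain proportions around the yolk (origin at the source-margin leading
  edge), ensemble averaging, midbrain–hindbrain boundary (MHB) estimation,
  log-normal fitting of cytoneme length distributions, and coverage/thickness
  metrics (`cytosim.analysis`);
- **scenarios** — named condition presets (control, ligand over-expression
  ×10, longer cytonemes with five contact events, the combination, and a
  partial rescue with half the cytoneme count), ensemble drivers,
  a calibration grid search, and CSV/JSON output (`cytosim.scenarios`).

A global ligand ledger (`loaded = in_tips + in_receivers + decayed + lost`)
makes conservation checkable to 1e-9 at every step.

## CLI

```bash
cytosim run --preset control --n-sims 20 --seed 1 --out out/control
cytosim run --config my_params.yaml --out out/custom
cytosim calibrate --out presets/            # grid-search growth/turnover params
cytosim fixtures --out fixtures/            # toy 12-cell tissue CSV
cytosim plot out/control                    # profile + length histogram PNG
```

`run` writes `cells.csv`, `cytonemes.csv`, `deposits.csv`, `profile.csv`,
`summary.json` (MHB bin, coverage, thickness, fitted length mean) and a
config echo that round-trips through `--config`.

## Reproducibility

Every run is driven by a single seeded NumPy generator with a fixed
entity-id iteration order: the same seed yields bitwise-identical deposit
logs, positions, and summaries. Ensembles use consecutive seeds from a base
seed.
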