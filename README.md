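# perturbkit

Analysis pipeline for temporal multiomic perturbation studies — built for
experiments that profile a drug response (here modelled on a cannabidiol
time course) with 11-plex isobaric (TMT) proteomics across subcellular
fractions, live-cell FRET biosensor dose–response screens, and quantitative
imaging assays. Every stage is exercisable end to end on synthetic data
with planted ground truth.

## What it does

- **Hierarchical Bayesian TMT differential expression** — reporter-ion
  ratios to a pooled global-mix channel are modelled as
  `y = beta[protein, label] + b[label] + eps` with per-label biases pooled
  over all proteins, solved by a blocked Gibbs sampler (5 chains,
  Gelman–Rubin R̂ < 1.05). Treated-minus-control differences are formed per
  draw (the global-mix denominator cancels), technical replicates combined
  in quadrature, biological replicates by Bayesian updating, and proteins
  selected by Cohen's d against replicate-count thresholds
  {6: 1.50, 5: 1.75, 4: 2.25, 3: 3.38} (α = 0.05, power 0.8).
- **FRET EC50 screens** — pixelwise FRET/CFP ratios from corrected images;
  per sensor × time, measurements scaled to [0, 1] and fit with
  `y = 1/(1 + exp(-k(x - EC50)))` on log10 dose; fits kept iff R² > 0.75
  against per-dose replicate medians and EC50 inside the dose range; kept
  values summarised by their median.
- **Differential Spearman correlation networks** — per-replicate edge
  values per condition, pooled-variance t-tests per pair, retention at
  `-log10 p > 2`, and stochastic-block-model clustering of the difference
  network.
- **Time-course statistics** — permutation spline F-tests with one pooled
  Benjamini–Hochberg pass across replicate-availability strata, and
  PCA-denoised anticorrelation calling of protein translocation between
  subcellular fractions (r < -0.8).
- **Imaging quantifiers** — apoptotic pixel fraction, filipin intensity sum
  above background, enzyme-kinetics initial rates on the 0–1 h window, and
  FRAP normalisation by a remote reference region.
- **Synthetic-data generators** (`perturbkit.synthdata`) — every input
  above, with planted effects, label biases, translocators, flipped network
  edges and exact image ground truth.

The fittable cores are scikit-learn-style estimators
(`TmtHierarchicalModel`, `LogisticEC50`, `StochasticBlockModel`,
`PCADenoiser`) with `fit`/`transform`, `get_params` and trailing-underscore
attributes; module-level functions wrap them.

## Worked example

Run the full synthetic study (simulation → every analysis stage) from one
seed:

```bash
perturbkit demo --seed 7 --out demo_out
```

This takes a few seconds and prints stage-by-stage progress. With seed 7 it
produces, among other outputs:

- `de_records.tsv` — 780 combined treated-minus-control records (60
  proteins × 13 observed time points), of which 67 exceed their effect-size
  threshold, selecting 12 proteins. Each row carries the posterior mean and
  sd of the log2 difference, its 95% credible interval, Cohen's d and the
  replicate count.
- `ec50_summary.json` — median EC50 9.66 µM over 18 kept sensor × time
  fits, with histogram bins of the kept-EC50 distribution.
- `edges.tsv` — 435 protein pairs tested between vehicle and treated
  panels; 12 edges retained at `-log10 p > 2` (8 pairs were simulated with
  their correlation flipped).
- `translocations.tsv` — of 100 simulated proteins, 18 pass the
  significance gate and 11 are called anticorrelated between two fractions
  at r < -0.8 (10 translocators were planted).
- `imaging_summary.json` — apoptotic fraction 24.3% (exact pixel truth for
  the simulated field), oxidase initial rates 99.5 and 49.8 intensity/h for
  wells simulated at 100 and 50, and a FRAP mobile-fraction amplitude of
  0.48 recovered exactly on the noise-free trace.

The same stages are available individually (`perturbkit simulate`,
`tmt-fit`, `fret-ec50`, `net-diff`, `timecourse`, `translocate`); see
`perturbkit --help` and `docs/schemas.md` for the file formats.

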