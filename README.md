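# seascapegen

A seascape-genetics toolkit for species with long-lived drifting larvae
(spiny lobsters are the motivating case). It connects three analyses that are
usually run in separate tools:

1. **Larval dispersal** — passive Lagrangian particle tracking through gridded
   ocean surface currents (`X(t+Δt) = X(t) + ∫ v(x,τ) dτ`, Euler or RK4), with
   coastal-settlement detection, per-site arrival fractions, and 1°×1°
   trajectory-density grids. Current fields can be loaded from NetCDF, built
   analytically, or derived from sea-surface height (geostrophy,
   `u = −(g/f)·∂η/∂y`, `v = +(g/f)·∂η/∂x`) and wind stress (Ekman response,
   `v_ek(z) = β(z)·τ·e^{iθ(z)}`).
2. **Microsatellite population genetics** — diversity indices (Na, Ho, unbiased
   He, rarefied allelic richness, PIC), Monte-Carlo exact Hardy–Weinberg and
   linkage tests, EM null-allele estimation with ENA-corrected Weir–Cockerham
   θ (FST) and bootstrap CIs over loci, three-level AMOVA
   (F_CT / F_SC / F_ST with permutation tests), and Mantel isolation-by-distance
   on FST/(1−FST) against great-circle distance.
3. **Seascape association** — distance-based redundancy analysis (dbRDA) of the
   pairwise-FST matrix on environmental covariates (SST, chl a, turbidity),
   PCNM spatial eigenvectors, and simulated larval-recruitment fractions, with
   forward selection, marginal permutation ANOVA, and adjusted-R² variance
   partitioning.

A seeded synthetic-data module generates a coherent "fixture world" (coastline,
boundary current with eddies, 15 release sites, hierarchically structured
genotypes with an admixed contact-zone population, latitude-driven
environmental gradients) so the entire pipeline runs with no downloads.

## Worked example

Run the full pipeline on the synthetic world:

```bash
seascapegen pipeline --seed 1 --out run1
```

or from Python:

```python
from seascapegen.cli_io import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(out_dir="run1", seed=1))
```

With seed 1 this prints a run report whose headline numbers are:

```
diversity  mean Ho over populations     0.588
fst        paired t (θ vs θ_ENA)        t = 12.35, p = 4.2e-22
amova      % variation                  4.06 among groups / 1.59 among
                                        populations within groups / 94.35
                                        within populations
           fixation indices             F_CT = 0.041, F_SC = 0.017, F_ST = 0.057
mantel     isolation by distance        r = 0.491, p = 0.001
disperse   mean settled fraction        0.241
dbrda      forward-selected predictors  sst_mean, pcnm2, recruits
           constrained proportion       0.737
```

Reading: the genotype generator was asked for a between-group F of 0.05, and
the AMOVA recovers most of that differentiation among the three groups
(F_CT = 0.041) with the expected dominance of within-population variance.
Genetic and geographic distance correlate (Mantel r = 0.49), and the dbRDA
attributes the site-to-site differentiation to the latitudinal SST gradient,
geography (a PCNM axis), and the simulated recruit fractions from the
dispersal stage — the same kind of decomposition one would report for a real
seascape-genetics study.

Per-stage outputs (locus summary, FST matrices, AMOVA table, Mantel result,
arrival table, density grid, dbRDA ANOVA and biplot scores) land in the output
directory as CSV/JSON. Each stage is also a standalone subcommand:
`seascapegen diversity | fst | amova | disperse | fixtures`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on the synthetic world (fixture
generation → diversity → FST/ENA → AMOVA → Mantel → dispersal → dbRDA), writes
the per-stage run report next to the output path, and writes the JSON summary
to `--out`. All randomness derives from `--seed`.
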