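# phenoplast

Analysis toolkit for intra-population functional variability in split-plot
drought experiments: relative-distance indices of phenotypic plasticity (PP)
and post-drought recovery (RE) per trait and family, a family-specific
log-linear model of stomatal conductance against predawn water potential,
two-way ANOVA of post-recovery gas exchange, and downstream hierarchical
clustering (with bootstrap support), PCA and FDR-corrected correlation
analysis. A seeded synthetic-data generator emulates the experimental design
(replicates x families x 2 watering regimes x blocks, stress and recovery
measurement phases) so the full pipeline runs without access to any measured
dataset.

## Data model

All stages exchange a tidy CSV with header

```
seedling_id,family,block,treatment,phase,trait,value
```

with `treatment` in `{WW, WS}` (well-watered / water-stressed), `phase` in
`{stress, recovery}` and `trait` drawn from a fixed vocabulary (`A_area`,
`A_mass`, `g_wv`, `iWUE`, `PNUE`, `Phi_PSII`, `SLA`, `N_m`, `C_m`, `d13C`,
`d15N`, `Psi_pd`, `RGR_T1`, `RGR_T2`, `RGR_Tot`). Validation enforces sign
classes, uniqueness of `(seedling_id, phase, trait)` and the restriction of
recovery-phase records to gas-exchange traits.

## CLI

Each stage is a subcommand of the `phenoplast` entry point:

```bash
phenoplast simulate --families 16 --reps 5 --blocks 2 --seed 1 --out table.csv
phenoplast indices --in table.csv --kind both --perm 1000 --seed 1 \
    --out indices.csv --tests tests.csv
phenoplast stomatal --in table.csv --out coefficients.csv --anova anova.csv
phenoplast anova --in table.csv --phase recovery \
    --traits A_area,g_wv,iWUE,Phi_PSII --out anova.csv
phenoplast multivariate --indices indices.csv --table table.csv \
    --coeffs coefficients.csv --b 1000 --seed 1 --out-dir results/
```

An end-to-end, fully seeded run is driven by one YAML config:

```bash
phenoplast pipeline run --config run.yaml
```

where `run.yaml` may set `out_dir`, design parameters (`n_families`,
`replicates`, `blocks`), `seed`, `n_perm`, `bootstrap`, `alpha`, an optional
`input_table` and per-stage toggles under `stages:`. The run writes a
`manifest.json` with the derived per-stage seeds and SHA-256 digests of all
inputs and outputs; two runs with the same seed are byte-identical.

## Library highlights

```python
import phenoplast as pp

design = pp.ExperimentDesign()            # 5 x 16 x 2 x 2 = 320 seedlings
table = pp.simulate(design, seed=1)
indices = pp.build_index_matrix(table)    # families x PP-/RE-trait columns
stat, p = pp.family_difference_test(table, "g_wv", "PP", n_perm=999, seed=1)
fit = pp.fit_loglinear(table)             # -ln(g_wv) ~ psi * family
anova = pp.sequential_anova(fit)
tree = pp.cluster_families(indices.matrix, B=1000, seed=1)
features = pp.build_family_features(table, indices, fit)
pca = pp.pca_families(features)
corr = pp.correlation_matrix(features, alpha=0.05)
```

Notes on method choices: the among-family test for PP/RE indices is a
seedling-label permutation test on per-pair relative distances (F-like
statistic); letter groups code confidence-interval overlap; cluster support
is a plain bootstrap probability over column resampling (not an
approximately-unbiased multiscale bootstrap); the FDR correction is
Benjamini-Hochberg.
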