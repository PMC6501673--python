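# collide

Analysis pipeline for nocturnal bird–building collision data: per-species
collision/checklist tallies, a χ² goodness-of-fit **collision disparity
index** (Pearson residuals binarized at ±3 into over-/under-represented
species), phylogenetically corrected logistic and Poisson regressions with
parametric-bootstrap confidence intervals and AIC model comparison, and
building-light models of nightly collision counts against a 0–17
illuminated-window score — plus a synthetic study generator with known
ground-truth effects so the entire pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `collide.data_model` | record types, CSV I/O, dataset validation |
| `collide.tallies` | inclusion filters, season windows, per-species tally indices |
| `collide.disparity` | χ² goodness-of-fit, Pearson residuals, ±3 binarization |
| `collide.phylo` | Newick I/O, 50% majority-rule consensus, species correlation matrix |
| `collide.regression` | phylogenetic logistic (latent liability, Firth penalty) and Poisson (Laplace) models, design builder, AIC comparison |
| `collide.light_models` | nightly counts vs light score: Poisson GLM, log-mean OLS, species-count-adjusted means |
| `collide.synthetic` | scenario generator: trees, traits, abundances, checklists, collisions, light-scored nights |
| `collide.pipeline` | orchestration, result bundle, report tables, CLI backend |

## CLI

```sh
# generate a synthetic study (optionally from a scenario.yaml)
collide simulate --seed 7 --out demo/

# run the full analysis
cat > run.yaml <<EOF
collisions: demo/collisions.csv
checklists: demo/checklists.csv
traits: demo/traits.csv
trees: demo/trees.nwk
nights: demo/nights.csv
n_boot: 100
seed: 7
EOF
collide run --config run.yaml --out demo/out

# print the fitted-model table
collide report demo/out
```

The result bundle contains `tallies.csv`, `disparity.csv`, `fits.csv` (+
`fits.json` sidecar with bootstrap CIs), `light_fits.csv`,
`consensus.nwk` and a `run_log.json` recording config hash and seed.
Reruns with the same inputs and seed are byte-identical.

## Model notes

- **Logistic disparity model.** Binary outcome = sign of a latent liability
  `Xβ + ε` with standard-logistic margins coupled by a Gaussian copula with
  correlation `λC + (1−λ)I`, `C` the shared-path phylogenetic correlation
  matrix. `λ = 0` reduces exactly to ordinary logistic regression. β solves
  a Firth-penalized estimating equation (robust to separation); λ maximizes
  a Gaussian pseudo-likelihood of standardized residuals; CIs are
  percentile parametric bootstrap (default 100 replicates).
- **Poisson count model.** `log-rate = Xβ + u`, `u ~ N(0, σ²C)`, marginal
  likelihood by Laplace approximation; `σ² = 0` reduces exactly to an
  ordinary Poisson GLM. The checklist-tally covariate enters as
  standardized `log(tally + 1)`.
- **Consensus.** Strict `>50%` clade retention (ties collapse to
  polytomies); branch lengths are the mean (configurable: median) over
  clade-supporting trees.
- Treatment-coding reference levels: `flight_call=no`, `habitat=edge`,
  `stratum=lower` (configurable via the design builder).
- Season windows default to 1 Mar–31 May and 15 Aug–30 Nov, configurable.
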