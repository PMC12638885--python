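# Methods

## Setting and model

`metstab` analyses a balanced multi-environment trial (MET): `G` genotypes
grown in `E` environments under a randomized complete block design with `R`
replicates (blocks) nested in environments. The default trait profile is the
horse gram set the package was built around — days to maturity (DM, days),
clusters/plant (NC), pods/plant (NP), pods/cluster (NPC), seeds/pod (NS) and
seed yield (YD, kg/ha) — with the study-scale design `G = 30, E = 6, R = 6`.

All stages share one generative view of a plot record:

```
y_ijr = mu + e_j + b_r(j) + g_i + (ge)_ij + eps_ijr
```

with environment `e_j` and block `b_r(j)` treated as fixed/nuisance terms and,
in the mixed-model stages, genotype `g ~ N(0, σ²g)`, interaction
`(ge) ~ N(0, σ²gei)` and plot error `eps ~ N(0, σ²e)` random.

The analysis sequence mirrors practice in variety evaluation:

1. **Trait screen** — Pearson correlations among per-genotype trait means
   across environments (p-values from the exact t transform with `n − 2` df,
   two-sided, unadjusted for the multiplicity of pairs); traits with a
   significant positive yield correlation at `α = 0.05` are kept, plus an
   explicit forced-keep list (maturity is typically force-kept on agronomic
   grounds even when its yield correlation is weak).
2. **YREM** — each cell mean divided by its environment's maximum;
   `1 − mean(YREM)` is the yield share lost to crossover interaction. Ties at
   the maximum all score 1; the average over environments is unweighted; ranks
   break ties by mean yield, then label order.
3. **Joint ANOVA + AMMI** — balanced two-way ANOVA (environment tested
   against the replicate-within-environment stratum; genotype and GEI against
   the pooled plot residual), then SVD of the double-centred cell-mean
   residual. All `K = min(G, E) − 1` axes are retained; scores are reported in
   the symmetric scaling `α√λ`. Axis tests use Gollob degrees of freedom
   `G + E − 1 − 2k` with plot-basis axis SS `R·λ²_k` against the pooled error —
   chosen because it is the standard closed-form axis test and makes the
   significance stars reproducible. Percent-of-SS is reported over
   G + E + GEI only.
4. **REML/BLUP** — for a balanced design the restricted likelihood factors
   over three orthogonal strata (genotype, interaction, residual) with
   expectations `σ²e + Rσ²gei + ERσ²g`, `σ²e + Rσ²gei`, `σ²e`. The REML
   criterion is maximized by L-BFGS-B on log-variances from the
   expected-mean-square (moment) start; at interior optima the solution equals
   the moment estimators exactly, and the log-parameterization keeps boundary
   (zero-variance) solutions well behaved. Stationarity is verified by a
   numerical gradient check when the line search cannot improve on an
   already-optimal start. Likelihood-ratio tests for each random term refit
   with that variance pinned at zero and refer `−2Δℓ` to χ²₁ — the
   conventional reporting scale; this is conservative at the boundary relative
   to the 50:50 mixture reference, which is noted rather than corrected.
   Genotype BLUPs use the balanced shrinkage identity
   `ĝ_i = h²_mean (ȳ_i − ȳ..)` with
   `h²_mean = σ²g / (σ²g + σ²gei/E + σ²e/(ER))` (heritability of genotype
   means; its square root is the selection accuracy). Interaction BLUPs shrink
   the double-centred cell residual by `Rσ²gei / (Rσ²gei + σ²e)` and are
   reported double-centred: the full Henderson solution adds a genotype-row
   component that is confounded with the genotype main effect, and projecting
   it out keeps the matrix a pure interaction summary (the tests verify the
   identity against a dense mixed-model-equation solve).
5. **Genetic parameters** — broad-sense `H² = σ²g/(σ²g+σ²gei+σ²e)`, GEI share
   `R²GEI = σ²gei/(σ²g+σ²gei+σ²e)`, within-environment GE correlation
   `r_ge = σ²gei/(σ²gei+σ²e)`, `h²_mean` and `As = √h²_mean`.
6. **WAASB / WAASBY** — SVD of the interaction BLUP matrix; WAASB is the
   average of absolute axis scores weighted by each axis's share of
   interaction variance, over all K axes (truncation is available but off by
   default since the weights already discount minor axes). Performance and
   WAASB are affinely rescaled to 0–100 (WAASB inverted: most stable → 100)
   and blended `WAASBY = (rY·θy + rW·θs)/(θy+θs)` with default weights
   65:35 favouring performance. All six traits are treated as larger-better in
   the rescale, including maturity (configurable). Mean-vs-WAASB quadrants
   split at the grand mean on x (the stated convention) and at the mean WAASB
   on y (no convention is stated for y; the mean is the symmetric choice and
   is recorded in the run manifest). Boundary cases join the high-mean /
   low-WAASB side.
7. **MTSI selection** — the genotype × trait WAASBY table is standardized
   (sample n−1 SDs), its correlation matrix eigen-decomposed, factors with
   eigenvalue > 1 retained (Kaiser), varimax-rotated (Kaiser row
   normalization), and scored by the regression (Thomson) method
   `F = Z R⁻¹ L`, the scoring used by the reference implementations of this
   index. The ideotype scores 100 on every trait, is standardized with the
   observed column means/SDs and scored with the same weights. MTSI is the
   Euclidean distance to the ideotype in factor-score space; selection keeps
   the `floor(intensity·G)` lowest (15% of 30 → 4). Per trait,
   `SD% = 100(Xs − Xo)/Xo` and `SG% = SD% · h²_mean` — the heritability of
   genotype means is the only definition under which the published
   differential/gain pairs are mutually consistent, so it is the contract.

## Synthetic data

The generator inverts the AMMI generative form. Genotype, environment, block
and error effects are Gaussian; the interaction is built from `gei_rank`
orthonormalized, column-centred Gaussian score pairs, hence exactly
double-centred with known rank — which is what lets the AMMI axis and
WAASB tests be validated against ground truth. It is scaled so
`Σ(ge)² = (G−1)(E−1)·σ²gei`, i.e. to the interaction stratum's degrees of
freedom; under this scaling the moment/REML estimator of `σ²gei` is unbiased
(scaling to the raw mean square over `G·E` cells would inflate recovered
components by `GE/((G−1)(E−1))`, +24% at 30×6). One consequence of exact
centring: the genotype stratum carries no interaction leakage, so the
genotype-variance estimator recovers `σ²g − σ²gei/E` rather than `σ²g`
(−1.1% at the default components); the recovery tests account for this known
offset.

A single integer seed feeds named sub-streams (genotype, environment,
interaction, block, error; one set per trait, genotype effects shared across
traits through a Cholesky factor of the trait correlation), so identical
seeds give byte-identical datasets and changing one component's draw does not
shift the others.

Defaults are the study conditions: 30×6×6, grand mean 938 kg/ha and yield
variance components `σ²g = 25425, σ²gei = 1663, σ²e = 2374` (kg/ha)². The
environment and block scales are nuisance terms that the published analyses
treat as fixed and never report; `σ²env = 1500` and `σ²block = 200` (kg/ha)²
were chosen once as realistic for a rainfed legume MET at this yield scale
(environmental main effects of the same order as the error scale, blocks an
order smaller) and are not tuned. `gei_rank = 2` matches the number of
interaction axes the published factor analyses retain.

What the generator does **not** emulate: non-Gaussian or heteroscedastic
errors, environment-specific error variances, unbalanced or missing plots,
spatial field trends, and year-to-year weather structure. Passing tests
therefore demonstrate correctness of the estimators and identities under the
balanced Gaussian model they assume — not robustness of the indices to the
messiness of real field data.

## Numerical choices

- Balanced-design sums of squares are computed from group means in closed
  form; SS additivity holds to 1e-8 relative and is asserted.
- REML convergence: L-BFGS-B, `ftol = 1e-14` on the negative restricted
  log-likelihood, bounds ±(40, 10) nats around the data variance scale;
  estimates below 1e-12 of the total variance snap to exactly zero.
- Negative moment estimates truncate to zero with a flag rather than erroring.
- Varimax: SVD-based iteration, tolerance 1e-10, Kaiser normalization on.
- Rescaling clips to [0, 100] to absorb 1-ulp floating overshoot.
- Degenerate inputs fail loudly: constant vectors cannot be rescaled,
  zero-variance traits cannot enter the correlation screen, all-zero variance
  components have no defined genetic parameters, unbalanced data are rejected
  by every closed-form stage.

## Problem sizes

The test suite and worked examples run at the study design (30×6×6; 1080
plots) and on 4–6-genotype toys where brute-force oracles (dense restricted
likelihood, Henderson equations, statsmodels ANOVA) are evaluated. The
stochastic calibration checks use 200 simulation replicates for variance
recovery and 200 for the boundary LRT size, sizes at which the Monte-Carlo
error of a median (≈2.4% relative) and of a binomial rate (≈1.5 points) are
small against the tolerances being checked.

## Known limitations

- Balanced, complete data only; no missing-plot imputation.
- Single-trait mixed models; the multi-trait step (MTSI) works on the
  derived WAASBY table, not a joint multi-trait fit.
- χ²₁ reference for boundary LRTs is conservative.
- The factor model is principal-component extraction with rotation, not
  maximum-likelihood factor analysis; oblique rotations are out of scope.
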