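# metstab

Multi-model stability analysis for balanced multi-environment trials (METs),
built around the selection workflow used for horse gram (*Macrotyloma
uniflorum*) mutant evaluation: a breeder has `G` genotypes grown in `E`
environments with `R` replicates and wants genotypes that are both high
performing and stable in the face of genotype-by-environment interaction
(GEI). The package implements the full pipeline as a tested library plus
numbered analysis drivers:

- **Trait screen** — Pearson correlations of genotype means; keep traits that
  travel with yield.
- **YREM** — yield relative to the environmental maximum,
  `Y_ij = X_ij / MAX_j`; `1 − YREM` measures yield lost to crossover GEI.
- **Joint ANOVA + AMMI** — `y_ij = μ + g_i + e_j + Σ_k λ_k α_ik γ_jk + θ_ij`;
  SVD of the double-centred interaction with Gollob axis tests.
- **REML/BLUP** — mixed model with random genotype and GEI
  (`g ~ N(0, σ²g)`, `ge ~ N(0, σ²gei)`), likelihood-ratio tests, shrunken
  genotype means `ĝ_i = h²_mean(ȳ_i − ȳ..)`, and genetic parameters
  (H², R²GEI, r_ge, h²_mean, As = √h²_mean).
- **WAASB / WAASBY** — `WAASB_i = Σ_k |IPCA_ik|·EP_k / Σ_k EP_k` from the SVD
  of the interaction BLUP matrix (lower = more stable), blended with 0–100
  rescaled performance as `WAASBY = (rY·65 + rW·35)/100`.
- **MTSI** — factor analysis of the genotype × trait WAASBY table (Kaiser
  retention, varimax), `MTSI_i = [Σ_f (F_if − F_f)²]^0.5` as distance to an
  all-100 ideotype; select the `floor(0.15·G)` best and report selection
  differential `SD% = 100(Xs − Xo)/Xo` and gain `SG% = SD%·h²_mean`.
- **Synthetic MET generator** — balanced RCBD data with known genotype,
  environment, block, error and low-rank interaction components, so every
  stage is testable against ground truth without field data.

See `docs/methods.md` for model details and the numerical choices.

## Worked example

The printed per-genotype summaries of the horse gram trials ship with the
package. `analysis/08_published_checks.py` recomputes the desk-reproducible
surface; the library calls behind it:

```python
from metstab import summary_stats, pearson_matrix, genetic_parameters
from metstab.mixed import VarianceComponents
from metstab.datasets import load_genotype_means, load_variance_components

means = load_genotype_means()
s = summary_stats(means["YD"])
# mean 938.09 kg/ha, SD 163.70, CV 17.45%  — the trial's yield summary row

cm = pearson_matrix(means[["DM", "NC", "NP", "NPC", "NS", "YD"]])
cm.r.loc["NC", "YD"]          # 0.83 — clusters/plant tracks yield closely

row = load_variance_components().loc["YD"]   # 25425 / 1663 / 2374 (kg/ha)^2
p = genetic_parameters(VarianceComponents(row.sigma2_g, row.sigma2_gei,
                                          row.sigma2_e, 6, 6))
(p.H2_broad, p.accuracy_As, p.r_ge, p.r2_gei)
# (0.863, 0.993, 0.412, 0.056): yield is strongly heritable, selection on
# genotype means is ~99% accurate, and GEI is a small share of variance
```

The full pipeline over a simulated study-scale MET:

```bash
python analysis/01_simulate_met.py   # 30 x 6 x 6, six correlated traits
python analysis/02_trait_screen.py
python analysis/03_yrem.py
python analysis/04_ammi_anova.py
python analysis/05_blup_gvc.py
python analysis/06_stability_waasb.py
python analysis/07_mtsi_selection.py
```

The last step prints, for example:

```
retained factors: 2 (eigenvalues 2.96, 1.02, 0.70, 0.62, 0.42, 0.28)
selected genotypes (lowest MTSI):
  G14: MTSI 2.668
  G08: MTSI 2.853
  ...
```

i.e. two latent factors carry the six WAASBY traits, and the four genotypes
closest to the ideotype are kept (15% of 30). Stage tables land in
`results/`. The same pipeline is scriptable (`metstab run --config cfg.yaml`,
`metstab synth`, `metstab gvc`) and callable as
`metstab.pipeline.run_pipeline`.

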