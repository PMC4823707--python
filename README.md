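# seqnoise

Noise diagnostics and differential-expression testing for sequencing count
data whose technical noise is **gamma-distributed at high read counts and
Poisson-distributed at low read counts**.

## The problem

Repeated sequencing of the same RNA sample (technical replication) does not
return identical read counts. Most count-based tools assume the technical
noise is Poisson, i.e. Var(Y) = E(Y). Across technical replicates of
small-RNA (miRNA) libraries, however, only the low-read genes behave this
way: for high-read genes the variance scales with the **square** of the
mean,

    Var(Y) ≈ μ² / k        (gamma with constant shape k)

which is the signature of a gamma distribution and is explained by the
stochastic exponential growth of PCR amplification. Tests that impose the
Poisson variance on high-read genes underestimate the true variance by a
factor of roughly μ/k and produce overwhelming numbers of false positives.

`seqnoise` provides, for a genes × samples count matrix with replicate
groups:

- **Diagnostics** — per-gene mean/variance across replicates, the OLS fit of
  log10(σ̂²+1) on log10(μ̂+1) (slope ≈ 1 ⇒ Poisson regime, slope ≈ 2 ⇒ gamma
  regime), and per-gene one-sample Kolmogorov–Smirnov goodness-of-fit tests
  against plug-in Poisson(λ̂) and Gamma(k̂, θ̂) models.
- **Differential expression** between two groups, on the raw count scale:
  - identity-link Poisson GLM Wald test,
    z = (μ̂₁−μ̂₀)/√(μ̂₀/n₀ + μ̂₁/n₁);
  - identity-link gamma GLM Wald test with Pearson dispersion φ̂,
    t = (μ̂₁−μ̂₀)/√(φ̂·(μ̂₀²/n₀ + μ̂₁²/n₁)), df = N−2;
  - cube-root transformation followed by a two-sample t-test (the
    Wilson–Hilferty cube root approximately normalizes gamma variates).
- **A PCR simulator** — a Galton–Watson branching process in which every
  molecule duplicates with probability p per cycle — with exact mean and
  variance formulas and a report on how gamma-like the amplified counts are.
- **A synthetic-data generator** (Poisson-gamma hierarchy:
  Y ~ Poisson(Λ), Λ ~ Gamma(k, μ/k), so Var = μ + μ²/k) that reproduces both
  noise regimes with one mechanism, plus ground-truth tables for power
  studies.
- **An evaluation harness** for type-I error, power, between-method
  agreement, and extreme-disagreement screens.

## Worked example

Generate a sextuplicate two-group dataset (500 genes, 10% differentially
expressed at fold change 4, gamma shape k = 10), diagnose its noise regime,
and test for differential expression:

```sh
cat > config.json <<'JSON'
{"n_genes": 500, "n_reps_per_group": 6, "mean_grid": [1.0, 5000.0],
 "gamma_shape": 10.0, "de_fraction": 0.1, "fold_changes": 4.0, "seed": 7}
JSON
seqnoise simulate-data --config config.json \
    --out-counts counts.tsv --out-truth truth.tsv
seqnoise diagnose --counts counts.tsv --groups counts.groups.tsv \
    --mean-threshold 10 --out-prefix diag
seqnoise de --counts counts.tsv --groups counts.groups.tsv \
    --pseudocount 0.5 --adjust bh --out de.tsv
```

The `diagnose` step prints the fitted high-read mean-variance line per
group:

```
group A: log10(var+1) = 1.915 log10(mean+1) - 0.837 (367 high-read genes)
group B: log10(var+1) = 1.928 log10(mean+1) - 0.895 (386 high-read genes)
```

A slope near 2 (not 1) says the high-read noise is quadratic in the mean —
gamma, not Poisson; the intercept ≈ −log10(k) reflects the dispersion. The
`de` step writes one row per gene per method:

```
gene_id   mean_g0  mean_g1  log2_ratio  method       statistic  df  dispersion  p_value    p_adjusted
gene001   155.0    199.0    0.3605      poisson_glm  5.7283     NA  NA          1.014e-08  2.651e-08
gene002   1868.0   1784.3   -0.0661     poisson_glm  -3.3911    NA  NA          6.96e-04   1.24e-03
```

`gene002` is a null gene (fold change 1 in `truth.tsv`): the Poisson test
calls it significant because it underestimates the variance ~180-fold at
this mean, while the `gamma_glm` and `crt_ttest` rows for the same gene are
non-significant. On matched null data the Poisson test rejects the majority
of high-read genes at α = 0.05; the gamma GLM and the cube-root t-test stay
near the nominal 5% and agree closely with each other (Spearman correlation
of −log10 p above 0.95).

The same operations are available as a library (`seqnoise.generate_matrix`,
`seqnoise.gof_scan`, `seqnoise.run_de_table`, `seqnoise.simulate_amplification`,
...); see the docstrings and `docs/methods.md`.

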