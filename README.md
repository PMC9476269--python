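# rccpsa

Continuous molecular subtyping and risk scoring of renal cell carcinoma
(RCC) from bulk gene-expression profiles.

Histopathology assigns an RCC tumor to one category — clear cell (ccRCC),
papillary (pRCC) or chromophobe (chRCC) — yet many tumors mix molecular
features of several subtypes, and those mixed tumors carry distinct risk.
`rccpsa` implements **proportional subtype assignment (PSA)**: instead of a
single label, each sample receives continuous proportions (c, p, h) of the
three subtypes, estimated reference-free from the sample alone. The ccRCC
proportion c then drives a prognostic index for cancer-specific survival
and a three-way risk stratification.

## The model

**Signature.** From a labeled training cohort, genes specifically
up-regulated in exactly one subtype (median fold change ≥ 2 against *both*
other subtypes, one-sided rank-sum test Holm-significant against both) are
ranked by their weaker pairwise fold change. The top 58 genes per subtype
form a 174 × 3 signature matrix of median linear expression per subtype.
The signature size is chosen by deconvolving an independent tuning cohort
with growing matrices and keeping the largest size that still changes the
assignments substantially.

**Deconvolution.** For a sample y over the signature genes (linear scale,
standardized) and standardized signature columns x_cc, x_p, x_h:

    y ≈ w_cc·x_cc + w_p·x_p + w_h·x_h      (no intercept)

with weights from Huber M-estimation (tuning constant 1.345, IRLS).
Negative weights are truncated and the rest rescaled to proportions with
c + p + h = 100 %. Goodness of fit is the Pearson correlation r between
y and its reconstruction; its significance P_psa comes from permuting y
across gene positions (B = 999, add-one estimator). Samples with
P_psa > 0.05 are set aside; samples with max(c, p, h) < 95 % are called
molecularly heterogeneous.

**Risk.** The ccRCC proportion (the RCC-R score) maps to the prognostic
index of a Cox model; the packaged published instance is

    PI = 14.71·c − 25.46·c² + 12.21·c³ − 1.46,    HR = exp(PI),

whose interior maximum near c ≈ 0.4 encodes that mixed ccRCC/pRCC tumors
carry the highest risk. The module refits such models (cubic polynomial or
restricted cubic spline, Efron ties), compares candidates by repeated
cross-validation / AIC / analysis of deviance, and learns good /
intermediate / poor cutpoints on the PI with a conditional-inference-style
survival tree (log-rank splits, Bonferroni-adjusted significance gates).

A seeded synthetic-data module generates reference cohorts with planted
markers, mixed cohorts on the simplex with lognormal noise, and survival
records driven by the published PI, so the whole pipeline is testable
offline.

## Worked example

```sh
printf 'n_genes: 400\nk_specific: 25\nn_samples: 60\n' > sim.yaml
rccpsa simulate --outdir fixtures --seed 3 --k 20 --config sim.yaml
rccpsa run --matrix fixtures/matrix.tsv --signature fixtures/signature.tsv \
    --survival fixtures/survival.tsv --permutations 999 --seed 7 --outdir out
```

which prints

```
wrote fixtures to fixtures
pipeline complete; outputs in out
```

`out/psa.tsv` / `out/scored.tsv` hold one row per sample — raw weights,
proportions, fit statistic, P_psa, call, PI and HR (abridged):

```
sample_id  prop_cc  prop_p  prop_h  fit_stat  p_psa  call
mix_0000   0.253    0.739   0.007   0.999     0.001  heterogeneous
mix_0001   0.000    0.000   1.000   0.999     0.001  unambiguous-chRCC
```

`mix_0000` mixes clear-cell and papillary features (c ≈ 0.25), so it is
called heterogeneous; its prognostic index PI ≈ 0.83 (HR ≈ 2.3) puts it in
the higher-risk stratum of `out/risk_groups.tsv` — on this small cohort
the tree finds two groups (good n=29, intermediate n=31, HR ≈ 4.1),
whereas larger cohorts typically split into three. The same steps are
available as library calls (`psa_cohort`, `prognostic_index`,
`find_risk_cutpoints`).

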