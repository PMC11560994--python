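# Methods

## Model and estimation

For a balanced multi-environment RCBD trial with G genotypes, E
environments and r blocks per environment, plot yield is modelled as

```
y_gek = μ + α_g + β_e + Σ_{n=1..N} λ_n γ_gn δ_en + q_ge + (block effect) + ε_gek
```

Estimation is two-stage and exact under balance. The additive part
(μ, α, β) comes from double-centering the G × E cell-mean table; the
interaction part is the SVD of the centered matrix, axis n carrying
singular value λ_n (descending), genotype vector γ_n and environment
vector δ_n. Everything downstream — per-axis SS, explained %, scores,
ASV — is a deterministic function of that SVD; there is no iterative
fitting, missing-cell imputation, or shrinkage.

Assumptions worth stating: complete, balanced tables (incompleteness and
unbalanced replication are hard errors, not silently averaged, because
the plot-basis SS conversion multiplies mean-basis SS by a common r);
fixed genotype and environment effects; i.i.d. plot error; blocks nested
within environments with no genotype × block stratum.

## Conventions

* **Score scaling.** Symmetric square-root scaling: both genotype and
  environment scores carry √λ_n, so the outer product of the scaled
  score vectors reconstructs the axis-n interaction term exactly and the
  sum of squared scores on either side equals λ_n. This is the only
  scaling under which the packaged trial's printed per-genotype scores
  and its printed per-axis SS are simultaneously coherent
  (Σ scores² ≈ 7.59 per side and r · 7.59² ≈ 172.9 for axis 1), and the
  test suite checks that coherence.
* **SS basis.** Per-axis SS are reported on the plot basis, r·λ_n²,
  matching how trial ANOVA tables are printed; the ASV weight
  SS₁/SS₂ = (λ₁/λ₂)² is basis-invariant.
* **Sign orientation.** SVD signs are arbitrary. The default rule flips
  each axis so the environment with the largest absolute score on that
  axis is positive; `orient="none"` keeps raw SVD signs. All reported
  scalars (SS, explained %, ASV, GSI, fitted values, selections) are
  sign-invariant, and comparisons against published score columns are
  made up to a per-axis sign because no single orientation rule
  reproduces every published axis.
* **F-test denominators.** Genotypes and GEI are tested against the
  plot-error MS. Environments are tested against the
  blocks-within-environments MS — locations are replicated by blocks —
  which is what published trial tables of this design imply; when only
  cell means are available and no block MS is supplied, the error MS is
  used as a fallback and the resulting environment F is marked by its
  magnitude as a different test.
* **Explained %.** Main-effect strata are expressed as a share of the
  total SS (all strata present in the table); interaction axes as a
  share of the GEI SS. `partition_means` can only total the strata it
  knows about, so its percentages shift slightly unless the error (and
  block) strata are supplied.
* **Gollob test.** Axis n gets df = G + E − 1 − 2n; MS = plot-basis
  SS/df; F against the supplied error MS; p from the F upper tail. The
  recommended axis count is the number of leading consecutive
  significant axes at α = 0.05 (user-overridable). Without error
  information the default retained count is 2, the biplot convention.
* **Ranks and ties.** ASV and yield ranks use competition ("min")
  ranking: ties share the smallest applicable rank, keeping GSI integer.
  Published GSI columns do not state a tie rule; this is the one place a
  deliberate convention was chosen rather than inferred.
* **Quadrants.** In AMMI2 coordinates a coordinate of exactly 0 counts
  as positive — deterministic, if arbitrary.
* **Numerical zeros.** Singular values below 1e−10 × λ₁, or below an
  absolute floor of 1e−12 × ‖table‖_F (so an exactly additive table
  reports zero available axes rather than machine noise), are treated as
  zero when counting available axes. ASV requires two nonzero axes and
  raises a degenerate-fit error otherwise; the pipeline reports the skip
  instead of failing.

## The packaged maize trial

The regression dataset is the published cell-mean table of a 2017 trial
of 69 maize hybrids at five Polish locations (RCBD, r = 3, yields in
t/ha at 14% moisture), stored exactly as printed (2 decimal places),
together with the published per-genotype IPCA1/IPCA2, ASV and GSI and
per-environment means and scores. Consequences of the 2 d.p. rounding:
recomputed SS agree with the published ANOVA to about ±0.2 (tests allow
±1.5), axis explained-% to about ±0.05 points, and fitted scores match
printed scores to ≤ 0.005. The plot-level records behind the table are
not published, so the published error stratum (MS 432.9/680, 680 d.f.)
ships as constants (`MAIZE_ERROR_MS`, `MAIZE_ERROR_DF`) to reproduce the
F-tests from cell means.

Known internal discrepancies of the reference columns, preserved as
printed rather than corrected:

* The published summary text gives a grand mean of 13.16 t/ha; the table
  itself gives 13.18, which the cell means confirm (13.1846).
* Genotype SMH_1724: its printed score row (−0.011, −0.081 → ASV 0.082)
  is arithmetically consistent with the printed cell means — our fit
  confirms it — yet the accompanying text calls SMH_1724 one of the
  *least* stable entries (0.919, duplicating SMH_1723's value) and the
  printed GSI column (87 for SMH_1724, 2 for SMH_1706) is only
  consistent with that larger value. Recomputed from the data, SMH_1724
  holds ASV rank 1, SMH_1706 rank 2, and the best GSI is therefore 3
  (SMH_1706), not the published 2. The package reports the recomputed
  values; the corresponding regression test records the published claim
  and fails, documenting the contradiction rather than hiding it.
* A handful of printed genotype means are off by one in the last digit
  from the mean of their printed cells (e.g. 14.736 printed as 14.73);
  the package always recomputes means from cells.
* The published per-environment top-4 selection lists correspond to
  N = 3 retained axes (19 of 20 picks match at N = 3, at most 12/20 at
  any other N); since the published axis count is unstated, selections
  are reported per N, not asserted.

## Synthetic generator

`generate_met` realises the model generatively: centered normal main
effects, an interaction Σ λ_k u_k v_kᵀ over random orthonormal zero-sum
axes (standard-normal draws, centered, QR-orthonormalised,
sign-canonicalised), normal block effects nested in environments, and
i.i.d. normal plot error, all from one seeded `numpy` generator — the
same seed reproduces a trial bit for bit. Defaults mirror the packaged
trial: G = 69, E = 5, r = 3, μ = 13.18 t/ha, α-sd 0.91 and β-sd 0.86
(back-calculated from the published SS: e.g. √(853.4/(r·E·(G−1))) ≈ 0.91),
λ = (7.6, 7.1, 6.0, 5.2) on the cell-mean basis, block sd 0.11 (from the
implied block MS ≈ 1.54 via the usual variance-component identity) and
plot-error sd 0.80 (error MS 0.64).

What the generator emulates — and does not. It produces exactly the
additive-plus-low-rank structure the estimator assumes, so noiseless
recovery is exact by construction and noisy recovery measures estimator
behaviour, not model misspecification. Real trials add what the
generator omits: spatial field trend, heteroscedastic and correlated
plot error, missing plots, genotype × block effects and non-normal
shocks. Passing recovery tests therefore validate the arithmetic and its
sampling behaviour under the stated conditions, not robustness of AMMI
on messy field data.

`recovery_study` repeats generate → collapse → fit over independent
child seeds and summarises bias, RMSE and relative RMSE of the recovered
singular values plus the Spearman agreement between planted and fitted
ASV ranks. Under the validation conditions used in the tests (G = 50,
E = 5, r = 3, λ = (6, 3), plot-error sd 0.3, 200 replicates) the leading
singular value is recovered with relative RMSE ≈ 3% and a small positive
bias (noise SS leaks into every axis), comfortably under the 5% design
target; the study sizes keep the whole suite in the seconds range.

## Limitations

Balanced, complete tables only (no EM imputation); fixed-effects ANOVA
only (no REML variance components); no GGE biplot variant, no
mega-environment polygon, and no alternative stability measures
(Wricke, Shukla, Eberhart–Russell). Gollob's F-test is known to be
liberal; it is provided because it is the convention this analysis
family uses, not as the best available axis-selection rule.
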