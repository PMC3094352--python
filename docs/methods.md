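# Methods

## Induction ratios

The package's central quantity is the induction ratio (IR) of a gene for one
patient at one injection: the ratio of the 12-h post-injection membrane
signal to the pre-injection signal, optionally after subtracting a per-record
background offset and/or dividing each signal by its membrane's total signal
(`compute_ir(..., background=..., normalize="total")`). The default is no
background and no normalization: the simulator emits clean signals, and for
user data both corrections are exposed because membrane-array protocols vary
in whether ratios are taken on background-subtracted or total-normalized
counts. All downstream statistics operate on the IR (raw scale) or its log2.

Conventions fixed throughout, with rationale:

* **Induction threshold IR ≥ 2.0, inclusive.** Repeat assays in untreated
  subjects vary by less than ~1.5-fold, so a two-fold change is comfortably
  outside assay noise.
* **Filter band [0.9, 1.1], closed, on the raw-scale cohort mean.** "Within
  ±10% of no change" reads naturally as a closed interval; the mean is taken
  on the ratio scale, not the log scale (a gene with IRs 0.25 and 4.0 has
  log-mean 0 but is plainly regulated). Filtering is recomputed independently
  at each time point.
* **Direction by strict majority.** A gene is upregulated when more than 50%
  of included subjects have IR > 1, downregulated when more than 50% have
  IR < 1; IR exactly 1.0 counts toward neither side, and an exact split is
  `undetermined`.
* **Patient exclusions are explicit flags** in the covariate table (viral
  infection at an injection, neutralizing antibodies), mirroring case-by-case
  clinical review, rather than auto-detected. Excluded patients contribute to
  no means, majorities, medians or model fits.

## Group comparison (ANCOVA least-squares means)

Per retained gene: ordinary least squares of

    log2(IR) ~ group(PR) + age + sex + gad_present + t2_volume

The least-squares mean of each group is the model prediction at the grand
means of all covariates, *including* the mean of the sex indicator (LS-mean
conventions differ; this one is stated explicitly and unit-tested against a
normal-equations oracle and statsmodels OLS). The group p-value is the
two-sided t-test of the group coefficient; adjusted means are back-transformed
to the IR scale as 2^(LS mean). The fit is vectorized — one shared design
matrix, all genes as response columns — so replicate-cohort simulations are
cheap; an exactly interpolated response (zero residual variance) is reported
as p = 1 rather than a 0/0 t-ratio.

A gene's response is **exaggerated** when, strictly, PR > GR for an
upregulated gene or PR < GR for a downregulated gene. Ties are never flagged
(the rule is directional), and undetermined-direction genes carry no flag but
remain in the binomial denominator, which is every gene outside the filter
band — conservative, since such genes can only count against the exaggeration
proportion. The cohort-level test is the exact binomial upper tail
P(X ≥ k | n, ½); at n ≈ 120 the exact tail is cheap, so no normal
approximation is used. Per-gene p-values are reported unadjusted (matching
the univariate convention of per-gene screening tables); a Benjamini–Hochberg
column is emitted alongside but not used for the headline proportion test.

The **magnitude of exaggeration** score for a patient is computed on the raw
IR scale: for each regulated gene with cohort median m (medians pooled over
both responder groups; per-group medians are available behind a flag),
the contribution is max(0, IR − m) for upregulated genes and max(0, m − IR)
for downregulated genes, summed over genes. Scores are compared between
groups by the same ANCOVA with the untransformed score as response (no
transformation is asserted; the score is a sum of many bounded-below terms
and is approximately symmetric at this panel size).

Group differences in the *number* of induced genes are tested by Poisson
regression (log-linear model, two-sided Wald test of the group coefficient).

## MRI responder classification

Matched-lesion tables (baseline and 6-month volumes, mm³) plus a new-lesion
count are consumed as produced by upstream registration/subtraction software.
Growth thresholds are inclusive: exactly 20% growth at ≥ 150 mm³, or exactly
50% below, counts as enlarging (boundary behaviour is tested both ways). A
zero-baseline record is treated as a new-lesion candidate, never enlarging.
PR ⇔ new + enlarging ≥ 3, also inclusive.

## Baseline-table statistics

Continuous characteristics use **Welch's** unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, computable from raw data or from
published n/mean/SD summaries — the Welch form, not the pooled form, is the
one that reproduces the published T2-volume p-value (0.02) from the printed
summaries. Categorical characteristics use Fisher's exact test; the two-sided
p follows the minimum-likelihood convention (sum over tables no more probable
than the observed one), verified against hypergeometric enumeration. Symptom
duration is a known awkward row: a Welch test on published-style summaries
does not reproduce the published value for that characteristic (a
transformation or nonparametric test was likely used), so the report prints a
caveat rather than guessing.

## The synthetic cohort generator

The generator's role is to provide tables with the statistical structure the
analysis assumes, with ground truth, at the study's scale. Defaults: 85
patients (15 poor responders), 166 genes, injections at months 0 and 6, five
patients per group additionally assayed at month 24.

Generative model on the log2-IR scale:

1. **Cohort gene profile.** 48/166 genes are unresponsive (target mean IR
   uniform in 0.96–1.04 — well inside the filter band, because the sampling
   spread of a cohort-mean IR at n = 85 is ~0.05); of the regulated genes,
   75% are upregulated (log2 target 0.26 + Exp(0.9), capped at 3.6, i.e. IR
   ≈ 1.2–12) and 25% downregulated (target IR uniform 0.45–0.85). Targets are
   defined for the *raw-scale* cohort mean, so the log2 fingerprint centre is
   Jensen-corrected by −(ln 2/2)·v using the per-gene predicted variance v;
   the noise part of v integrates E[(1−r)/r] over the correlation-target
   distribution with a 1.15 allowance for the convexity of the raw-scale mean
   in the per-patient variance.
2. **Patient fingerprints.** F_p = mu + d_p with deviation SD s_p for
   regulated genes, where s_p is lognormal (median 0.45, sigma 0.40) — this
   patient-to-patient spread in fingerprint breadth is what makes
   induced-gene counts vary between patients (typically ~25–110 at the
   default settings). Unresponsive genes get a small fixed deviation SD
   (0.15): genes unregulated in the cohort carry little patient-specific
   response structure. Deviations are independent across genes; the generator
   deliberately has **no shared per-patient responsiveness factor**, because
   a shared directional factor would correlate the signs of per-gene group
   contrasts and destroy the nominal type-I error of the binomial
   exaggeration test under the no-effect condition. The cost is that the
   extreme low induced counts (≈ 7) seen in real patients arise here only via
   the viral-infection special cases.
3. **Exaggeration.** Poor responders' regulated-gene fingerprint values are
   multiplied by `exaggeration_factor` (default 1.4) on the log2 scale —
   upregulated genes pushed further up, downregulated further down. The
   default was calibrated once, by Monte-Carlo over seeds, so that ≈ 80% of
   regulated genes end up flagged as exaggerated by the downstream analysis.
4. **Stability by construction.** The fingerprint is reused at every time
   point; each injection adds independent noise with per-patient SD solved in
   closed form, sigma_p = sqrt(Var_g(F_p)·(1−r_p)/r_p), from a per-patient
   target r_p ~ N(0.81, 0.11) truncated to [0.30, 0.97]. Setting `noise_sd`
   overrides this with a fixed per-signal log2 noise SD.
5. **Signals.** Per-gene abundances are lognormal (median 800, log2-SD 1.2);
   pre = abundance·2^ε₁ and post = abundance·2^(F+ε₂) with each ε carrying
   half the IR noise variance, so post/pre reproduces the intended IR up to
   noise. The pre-injection expression distribution of IRGs is not an
   empirical quantity here — it is a modelling choice, and nothing downstream
   depends on its location because every statistic works on ratios.
6. **Covariates and lesions.** Covariates are drawn per group from the
   published baseline-table distributions (age and T2 volume normal with the
   printed means/SDs, sex and gadolinium presence Bernoulli with the printed
   percentages). Lesion tables are constructed so the MRI rule recovers the
   true label exactly: poor responders receive ≥ 3 new/enlarging lesions,
   good responders ≤ 2, enlarging lesions are drawn on both sides of the
   150 mm³ breakpoint with growth strictly beyond the branch threshold, and
   stable lesions strictly below it.
7. **Special cases.** `generate_special_cases` appends two viral-infection
   patients (pre-injection expression already at the induced level at
   baseline, hence flat IRs and < 7 induced genes at that injection) and one
   neutralizing-antibody patient (normal baseline response, flat at
   6 months, hence between-injection correlation near 0), all flagged for
   exclusion. With zero special cases requested the output is bit-identical
   to `generate_cohort`.

All randomness flows from one `numpy.random.Generator` seeded from the
config; the same config yields bit-identical tables.

### What the simulator does and does not emulate

It reproduces: the sample sizes and group fractions, the covariate
distributions, stable individual fingerprints with the observed
between-injection correlation, wide variation in induced-gene counts, a
filter-band removal count near 48/166, and a directionally exaggerated PR
response affecting ≈ 80% of regulated genes. It does **not** emulate:
between-time-point changes in which genes respond (fingerprints are
time-invariant, so both injections remove a similar number of genes, unlike
the 48-vs-30 asymmetry real leukocyte-population shifts produce); correlation
between covariates and expression (covariates are pure noise consumers in the
ANCOVA, so covariate adjustment is exercised but not stressed); spot-level
artifacts or missing values; and any association between exaggeration and
induced-gene *counts*. Passing tests on synthetic cohorts therefore
demonstrate the pipeline's correctness and operating characteristics under
the stated model, not the biological findings themselves.

## Problem sizes and numerical choices

Replicate-based checks use 200 synthetic cohorts per arm at the full 85 × 166
study scale (the vectorized ANCOVA makes one cohort ≈ 0.1 s). The type-I
check accepts 2–8% rejections at α = 0.05 over 200 replicates (±2 binomial
SDs around the nominal 5%, and the exact binomial critical value at n ≈ 118
makes the test slightly conservative, ~4%). Fisher enumeration checks cover
tables with totals ≤ 32; binomial enumeration covers n ≤ 12. Exactly
interpolated ANCOVA responses (residual variance at rounding-noise level)
report p = 1. Rank-deficient designs raise an error naming constant columns
rather than silently pseudo-inverting.

## Known limitations

* `ancova_lsmeans_all` requires complete IR matrices over retained genes;
  pairwise-complete per-gene designs are not implemented (the simulator emits
  complete data; real data with failed spots should be filtered first).
* The per-gene ANCOVA treats genes independently; no multiplicity correction
  is applied to the headline proportion test (by design), and the binomial
  test inherits the independence-across-genes assumption of the original
  analysis.
* The magnitude score is dominated by strongly induced genes because it is
  summed on the raw IR scale; that is intentional (matching the definition)
  but makes the score scale-dependent on the gene panel.
* Lesion matching across time points is assumed done upstream; this package
  never touches images.
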