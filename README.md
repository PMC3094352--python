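# ifnresponse

Analysis toolkit for the pharmacodynamic (molecular) response to
interferon-beta (IFNβ) in multiple sclerosis, built around membrane-macroarray
**induction ratios** of interferon-regulated genes (IRGs), plus a synthetic
cohort simulator for developing and validating the pipeline without patient
data.

## The scientific problem

IFNβ reduces disease activity in relapsing-remitting MS, but 20–25% of
patients continue to accrue new brain lesions on therapy and there is no
validated biomarker of treatment response. One way to probe this is
pharmacodynamic: draw blood immediately before and 12 h after an IFNβ
injection, measure the expression of a panel of IRGs both times, and summarize
each gene's response as an **induction ratio**

    IR_g = post-injection signal of gene g / pre-injection signal of gene g

so IR > 1 means induction, IR < 1 repression, and IR ≥ 2 defines an *induced*
gene. Treatment response is classified from MRI: a patient with **≥ 3 new or
enlarging T2 lesions** at 6 months is a poor responder (PR), otherwise a good
responder (GR); an enlarging lesion must grow ≥ 20% if its baseline volume is
≥ 150 mm³, or ≥ 50% if smaller.

The analyses this package implements, for a cohort assayed at baseline,
6 months and (for a subset) 24 months:

* **Response fingerprints and their stability** — per patient, the Pearson
  correlation of log2 IRs across genes between injections.
* **Gene filtering and direction** — genes whose cohort-mean IR lies in the
  closed band [0.9, 1.1] are removed as unregulated; remaining genes are
  upregulated/downregulated by a strict majority of subjects with IR above/
  below 1.
* **Exaggeration analysis** — per retained gene, covariate-adjusted
  least-squares means of log2 IR (ANCOVA on responder group with age, sex,
  gadolinium-lesion presence and T2 volume as covariates), back-transformed to
  the IR scale. A gene is *exaggerated* when the PR adjusted mean is further
  from no-change in the gene's regulated direction; whether exaggerated genes
  exceed half of the regulated panel is tested with an exact one-sided
  binomial test against proportion ≤ 0.5.
* **Magnitude of exaggeration** — per patient, Σ over regulated genes of the
  directional excess of the patient's IR over the cohort median, compared
  between groups with the same ANCOVA.
* **Descriptive statistics** — Welch t-tests (raw data or published
  n/mean/SD summaries), Fisher exact tests, a Poisson regression of
  induced-gene counts on responder group.
* **Synthetic cohorts** — a generator reproducing the study conditions
  (85 patients, ~18% PR, 166 genes, stable per-patient fingerprints with
  between-injection correlation 0.81 ± 0.11, directionally exaggerated PR
  responses) with full ground truth for recovery testing.

## Worked example

```python
import ifnresponse as ifr
from ifnresponse.pipeline import analyze_cohort

cohort = ifr.generate_cohort(ifr.SimulationConfig(seed=1))
res = analyze_cohort(cohort)
tp0 = res.timepoints[0]
```

prints (via the snippet in `scripts/acceptance.py`-style reporting):

```
responders: {'GR': 70, 'PR': 15}
stability of log2-IR fingerprints (baseline vs 6 months): 0.80 +/- 0.10
genes filtered out at baseline (mean IR in 0.9-1.1): 48
exaggerated genes: 99/118 (84%), binomial p = 1.5e-14
magnitude-of-exaggeration ANCOVA: GR 50.4 vs PR 218.1, p = 7.1e-21
```

Reading this: the MRI rule recovers the generated 70/15 split; each patient's
molecular fingerprint is highly reproducible between injections six months
apart (mean r = 0.80); 48 of 166 genes show no cohort-level response and are
filtered; of the 118 regulated genes, 84% respond more strongly (in their
regulated direction) in poor responders than the binomial null of 50% allows,
and the per-patient exaggeration-magnitude score is far higher in poor
responders after covariate adjustment.

The same workflow is available from the shell:

```sh
ifnresponse simulate --out cohort/ --seed 1
ifnresponse compute-ir --intensities cohort/intensities.tsv --out ir.tsv
ifnresponse classify-mri --lesions cohort/lesions.tsv --out labels.tsv
ifnresponse analyze --ir ir.tsv --covariates cohort/covariates.tsv \
    --labels labels.tsv --timepoint 0 --out analysis/
ifnresponse report --ir ir.tsv --covariates cohort/covariates.tsv \
    --labels labels.tsv
```

## Layout

| module | contents |
| --- | --- |
| `ifnresponse.simulate` | `SimulationConfig`, `generate_cohort`, `generate_special_cases` |
| `ifnresponse.induction` | `compute_ir`, `IRMatrix`, induced counts, stability correlations |
| `ifnresponse.genes` | noise filter band, majority-rule direction classification |
| `ifnresponse.exaggeration` | ANCOVA LS means, exaggeration flags, binomial test, magnitude score, Poisson count test |
| `ifnresponse.mri` | lesion-growth rule, good/poor responder classification |
| `ifnresponse.baseline` | Welch t (raw or summary), Fisher exact, baseline table report |
| `ifnresponse.pipeline` | `analyze_cohort` / `analyze_timepoint` orchestration |
| `ifnresponse.cli` | `ifnresponse` command with `simulate`, `compute-ir`, `classify-mri`, `analyze`, `report` |

See `docs/methods.md` for the statistical model, the simulator's assumptions
and known limitations.
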