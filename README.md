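# uveprof

Chronic uveitis is the most serious comorbidity of juvenile idiopathic
arthritis (JIA): it is usually asymptomatic in young children and can cost
them their vision, so rheumatologists screen for it on a schedule driven by
known risk factors (young age at arthritis onset, oligoarticular onset, ANA
positivity).  `uveprof` implements, as a reusable and fully tested pipeline,
an EHR text-mining study design that profiles such risk factors directly
from what is already recorded in clinical care: dictated notes and ICD-9
coded encounters from a pediatric rheumatology clinic.  It is aimed at
clinical-informatics researchers who want to evaluate practice-based
evidence pipelines of this kind end to end — including their failure modes
— without access to a hospital data warehouse.

## What the pipeline does

1. **Annotation** (`uveprof.annotate`) — exact, word-boundary term matching
   of a curated lexicon against note text, with NegEx/ConText-style rules
   that flag negated mentions ("no evidence of uveitis") and family-history
   attributions ("mother with psoriasis"), reduced to a patient × concept
   matrix of first affirmative mention dates.
2. **Dual-layered cohort selection** (`uveprof.cohort`) — a patient counts
   as a JIA case of chronic uveitis only when ICD-9 codes (364.1x) *and* an
   affirmative uveitis mention agree; acute-only uveitis (364.0x) and
   thinly documented patients (< 25 notes) are excluded.
3. **Association testing** (`uveprof.stats`) — per-factor 2×2 Fisher exact
   tests and Wald odds ratios; demographic balance via an enumerated r×c
   Fisher exact test and Welch's t; a multivariate logistic model fitted by
   IRLS with bidirectional stepwise AIC selection, with age, gender and
   race forced in:

   logit P(uveitis | x) = β₀ + β_age·age + β_g·gender + β_r·race + Σ_f β_f·x_f

   The headline factor is allergy-medication exposure (medication
   reconciliation makes drug mentions a reliable proxy for allergic
   conditions), with diphenhydramine counted only when mentioned strictly
   before the uveitis diagnosis, because it is also given prophylactically
   with the biologics used to treat uveitis.
4. **Residual-feature clustering** (`uveprof.cluster`) — concepts not used
   in selection or association, restricted to each patient's pre-diagnosis
   window, clustered agglomeratively (complete linkage, Euclidean distance)
   with Newick export, a most-case-enriched "main cluster" scan, and
   permutation-calibrated enrichment significance.

Because no real corpus ships with the package, `uveprof.synthetic_ehr`
generates one: 602 JIA-coded patients (42 chronic-uveitis cases, 4
acute-only, 255 eligible controls, 301 low-documentation controls) with
realistic demographic margins, a median arthritis-to-uveitis delay of 282
days, template-based notes carrying affirmative/negated/family mentions,
and a complete ground truth for every embedded mention — so every stage is
verifiable against what the generator planted.

## Worked example

```bash
uveprof run-all --seed 2013 --out-dir out/
```

runs the whole pipeline on the packaged synthetic fixture and prints the
report.  Abridged output from that exact command:

```
- cases (chronic uveitis): 42
- controls: 255
- excluded (acute_only): 4
- excluded (too_few_notes): 301
- median arthritis-to-uveitis delay: 282 days
...
- allergy_drug: OR 2.94 (1.51-5.74), p=0.001709   # bivariate
...
- ana_positive: adjusted OR 5.49 (2.25-13.36), p=0.0001759
- rf_positive: adjusted OR 0.07 (0.01-0.64), p=0.01887
- allergy_drug: adjusted OR 3.43 (1.40-8.39), p=0.006892
- allergy_terms: eliminated by stepwise selection
...
- main cluster: 13 cases / 5 controls (enrichment p=7.7e-09,
  permutation-calibrated p=0.005)
```

Reading it: the dual-layered selection reproduces the intended cohort
composition exactly; allergy-drug exposure is positively associated with
chronic uveitis before and after adjustment while the weaker, collinear
allergy-term variable is eliminated by stepwise selection; ANA positivity
and oligoarticular onset come out as risk factors and RF positivity as
protective; and even after removing every analysis concept, future uveitis
patients still co-cluster on residual note content (beclomethasone,
hypersensitivity, contact dermatitis driving the cluster).

The same artifacts land in `out/` as plain-text tables (`cohort.tsv`,
`factors.tsv`, `bivariate.tsv`, `multivariate.tsv`, `influence.tsv`,
`dendrogram.nwk`, `report.md`).

## Layout

```
src/uveprof/        lexicon, synthetic_ehr, annotate, cohort, stats,
                    cluster, pipeline, cli
tests/              unit + property + acceptance suites
docs/methods.md     models, conventions, calibration and limitations
scripts/acceptance.py
```
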