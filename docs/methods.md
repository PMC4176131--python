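# Methods

This note records the models, conventions and calibrations behind
`uveprof`, in the order the pipeline runs, together with what the
synthetic corpus does and does not establish about real clinical data.

## Vocabulary and "derivatives"

The lexicon is a fixed, curated vocabulary: ICD-9 code sets for JIA
(696.0, 714.0, 714.2, 714.3, 714.9, 720.2, 720.9) and for acute (364.0x)
versus chronic (364.1x) uveitis, diagnosis-confirmation term sets,
risk-factor term sets, and an allergy-medication table mapping the
brand names dictated in notes (Flonase, Zyrtec, Benadryl, ...) to generics
and medication classes.  Generic names are included alongside brands
because medication reconciliation records either form.

Term "derivatives" are produced by a deterministic suffix-rule table
rather than a stemmer, so matching is reproducible bit-for-bit:
single-word terms longer than three characters gain a plural
(consonant-y → "-ies", otherwise "-s"; terms already ending in "s" are
left alone) and "-y" terms gain the "-ic" adjectival form
(allergy → allergic).  The rules are applied to a fixpoint, making
expansion idempotent by construction.  Which derivative forms the original
clinic pipeline matched is unknowable from the outside; this table is our
convention and is deliberately small.

ICD-9 matching is prefix-based: a set rooted at `364.1` matches its
five-digit children `364.10`–`364.19`, which is what keeps the acute and
chronic families disjoint.

## Annotation

Matching is case-insensitive exact string matching at word boundaries;
overlapping candidates resolve longest-match-first, then leftmost, so a
match never fires inside a longer accepted term.  Context detection uses
compact NegEx/ConText-style trigger lists, fully enumerated in
`annotate.py`: pre-negation triggers within **6 tokens** before the
mention in the same sentence (scope cut by "but"/"however"/...),
post-triggers ("was ruled out", "unlikely") within 6 tokens after,
pseudo-triggers ("no increase", "not only") blocking, and family triggers
("mother", "family history of", ...) anywhere earlier in the sentence.
Sentences break at `.`, `!`, `?` and newlines.  The 6-token window and the
trigger inventories are stated conventions: the underlying rule systems
are named in the study design but their parameters are not, and the
synthetic corpus only emits trigger-conform text.  Consequently the
near-perfect flag accuracies measured here certify the implementation,
not performance on real prose — real notes contain trigger variants,
section headers and misspellings this rule set does not cover.

The patient–feature matrix keeps, per patient and concept, the earliest
non-negated non-family mention date and, separately, the earliest
family-attributed date.  Family attribution is consumed only by the
psoriasis factor (self **or** first-degree relative counts as exposed).

## Cohort conventions

* Age at diagnosis = (first JIA-coded encounter − birth date) / 365.25,
  and the under-16 filter applies at the first JIA code.
* "First 6 months after diagnosis" = 183 days (oligoarticular onset).
* The 25-note floor applies to every JIA patient; in the default fixture
  all cases clear it, matching the documented selection arithmetic.
* A chronic-coded patient whose notes never affirm uveitis is excluded as
  unconfirmed rather than kept as a control, since controls must be free
  of chronic-uveitis codes.
* Analysis windows: cases end the day before the first chronic-uveitis
  code; controls end at the arthritis date plus the median case delay, so
  both cohorts contribute comparable spans of pre-outcome documentation.
  Only the clustering stage restricts features to these windows; the
  association stage restricts only diphenhydramine (to pre-diagnosis
  mentions in cases), because that is the single stated temporal
  restriction of the study design.  A `window_restrict_all` switch exposes
  the stricter variant as a sensitivity analysis.

## Statistics

Fisher tests use the probability-mass two-sided rule: sum the
probabilities of all tables with the observed margins whose probability is
at most the observed one times (1 + 1e-7).  The r×c version enumerates
tables over the free cells (the 4×2 race table needs ≈14k candidates) and
falls back to seeded Monte Carlo with fixed margins when enumeration is
infeasible.  Both the 2×2 and r×c paths are verified against each other,
against scipy, and against exact-rational oracles.

Odds ratios are sample ORs (ad/bc) with Haldane–Anscombe +0.5 on all cells
when any cell is zero and 95% Wald intervals.  Exact conditional intervals
are out of scope, so printed interval endpoints of the source study are
not expected to match bit-for-bit.

Logistic models are fitted by IRLS (convergence when the max coefficient
change drops below 1e-8, cap 50 iterations); a coefficient escaping ±15
flags quasi-separation and returns a non-converged fit instead of raising.
Stepwise selection is bidirectional by AIC from the forced-only model
(age, gender dummy-coded against Female, race against White), forced terms
never dropped, ties broken by candidate order — AIC is chosen as the
reproducible criterion since the study names none.

## Synthetic corpus: what it encodes

The fixture's composition is exact, not sampled: 42 cases + 4 acute-only +
255 eligible controls + 301 low-note controls = 602; gender and race
margins are assigned as exact counts per cohort; uveitis delays are
inverse-CDF draws of a log-normal centred on 282 days (log-sd 0.6, a
documented choice) at symmetric plotting ranks with the central order
statistics pinned to 282, so the sample median is exactly 282.  Note
counts are 25 + Poisson(mean − 25) for eligible patients (means 60.9 /
55.4) and a clipped Poisson below 25 for low-documentation controls.
Ages are truncated normals (means 7.2 / 10.2 years, sd 3.0, support
1–15.95) so cases are diagnosed younger.

Exposure counts are exact per factor.  The allergy-drug table (25/42
cases, 85/255 controls) solves the reported bivariate OR 2.92; the
allergy-term table (20/42, 76/255) solves the reported OR 2.14, with the
20 term-positive cases nested inside the 25 drug-positive cases and 71 of
76 term-positive controls nested inside the drug-positive controls — this
collinearity, with the drug variable genuinely stronger, is what makes
stepwise selection eliminate the term variable, as the study describes.
Three of the five term-negative drug-exposed cases mention an allergist
(not a lexicon term), two mention the drug alone.  Remaining factor counts
(ANA 25/50, oligoarticular 25/70, psoriasis 10/25 — 40% via family mention
only, RF 1/30, sinusitis 10/35) reproduce the reported effect directions
and approximate magnitudes; they are conventions, since the corresponding
proportions are not printed.  A configurable number of unexposed cases
(default 3) carry a post-diagnosis Benadryl mention only, exercising the
diphenhydramine restriction: they must not be counted as exposed, and the
end-to-end tests check extracted counts equal planted counts exactly.

Residual concepts drive the clustering stage: four signal concepts
(beclomethasone, contact dermatitis, folliculitis, hypersensitivity)
planted at ~0.45–0.55 in cases versus ~0.10 in controls, plus five noise
concepts at 0.35 in both.  Setting `residual_signal=False` equalises the
rates, giving a null corpus for calibration tests.

Replicate cohorts (for parameter recovery) draw 42 cases and 255 controls
with exposures conditionally independent given case status at per-factor
log-odds, **except** allergy terms, which depend on drug exposure only
(P = 0.65 with a drug mention, 0.12 without).  Under conditional
independence the implied prospective model is exactly logistic with
coefficients equal to the per-factor log odds ratios, so the calibrated
drug coefficient ln 2.54 is the estimand the stepwise refit should
recover, and the true adjusted term coefficient is zero — elimination of
the term variable is the generating truth, not an artifact.  When a
replicate's stepwise model drops the drug term, its adjusted OR is taken
from the final model refit with the drug term added back, so the reported
median is always defined.

Measured behaviour worth knowing: at 42 events and ~12 model parameters
the ML estimate of the drug log-OR carries the classic finite-sample
inflation away from zero (≈ +6% on the median across replicate sets, seen
even when fitting the exact generating model).  Firth-type bias reduction
would remove it but is deliberately out of scope; the recovery test's 15%
tolerance absorbs it.

## Main-cluster identification

The study identified its main cluster visually from a phylogram; an
algorithmic stand-in has to be explicit.  `find_main_cluster` scans every
internal dendrogram node with at least `min_size` (default 5) leaves whose
case fraction exceeds the cohort baseline and returns the node with the
smallest two-sided Fisher enrichment p (ties: larger cluster, then lower
merge height).  Two caveats are deliberate:

* the size floor exists because a two-leaf all-case node reaches p ≈ 0.02
  under any null, which would make the scan meaningless;
* the scan minimum over hundreds of nested candidates is *not* a p-value —
  on null corpora it falls below 0.05 in the large majority of label
  shuffles.  `main_cluster_permutation_p` therefore refers the observed
  scan minimum to its own permutation distribution over seeded label
  shuffles; the calibrated p is uniform under the null (measured: 1/100
  shuffles significant on a null corpus) and small on the signal corpus
  (0.005 at 199 permutations, the resolution floor).

The exact 20-versus-3 composition of the original study's cluster is not
treated as reproducible: it depends on the real corpus and on an unstated
tree-cutting rule.  What the pipeline reproduces is the qualitative claim:
future uveitis patients co-cluster on residual pre-diagnosis text, with
the planted concepts dominating the feature-influence ranking.

Complete linkage is the default (the default of the clustering routine in
the statistical environment the study names); single and average linkage
are available behind the same interface.  Merging is deterministic: exact
distance ties merge the smallest node-id pair.

## Known limitations

* Trigger lists and templates are co-designed: annotation metrics on the
  fixture are upper bounds, not estimates of real-world accuracy (the
  original pipeline reported 74% sensitivity / 96% specificity on a
  manually annotated corpus, which is out of reach without that corpus).
* Demographic-balance p-values printed in the source study (0.147 gender,
  0.203 race) are not reproducible from its own printed tables — R's
  `fisher.test` and this package both give 0.216 / 0.221 — and the study
  elsewhere states "both P > 0.7" for the same comparisons.  The package
  reproduces the *test*, not the printed numbers.
* The "number needed to screen" figure of the source study is not
  implemented; its combination rule is not derivable from the stated
  sensitivities and prevalence.
* Exact conditional CIs, Firth correction and multiple-testing adjustment
  are intentionally absent, matching the study's analysis plan.
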