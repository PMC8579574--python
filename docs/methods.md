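# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, and what the synthetic data can and cannot show.

## Study population and labeling

The target population is adults with hypochromic microcytic anemia:
MCV < 80 fL, MCH < 27 pg, and sex-specific anemia (Hb < 12 g/dL women,
< 13 g/dL men), with severe anemia (Hb < 8 g/dL) excluded. Gold-standard
labels are confirmatory-marker rules: HbA2 > 3.5 % ⇒ β-thalassemia trait
(βTT), serum ferritin < 15 ng/mL ⇒ iron deficiency anemia (IDA). All
thresholds are implemented as strict inequalities exactly as stated
clinically; a record equal to a threshold is rejected with an explicit
reason, and records meeting both label rules ("simultaneous presentation")
or neither are rejected as `ambiguous`/`unlabeled`. The filter is
idempotent and partition-complete (|input| = |kept| + |rejected|), and every
rejection carries a machine-readable reason so exclusions are auditable.
Serum iron and TIBC are carried but never used by any rule; no imputation
or unit conversion is attempted.

Class balance is summarised by normalized Shannon entropy H(p)/log k
(1 = perfectly balanced, 0 = single class, with the k = 1 case defined as
0). The reference composition 708 βTT / 470 IDA gives 0.9704.

## The index registry

Each of the 43 discrimination indices is a record
`{name, expression, cutoffs, btt_side, source}`. Formulas are data — parsed
once by a small expression engine restricted to `+ − * / **`, unary minus,
`abs()`, numeric constants, CBC field names, and 0/1 comparison terms
(`a < b`). The comparison terms exist for composite scores: the Janel (11T)
score is the count of eleven component tests voting βTT, which is
expressible only with indicators. Division by zero and missing fields raise
errors naming the cause; NaN predictions are never emitted.

Decision rule: βTT is predicted when the value falls on `btt_side` of the
cutoff (`below`, `above`, or `outside-interval` with a two-element cutoff
pair). A value exactly at a cutoff goes to the non-βTT side — a
deterministic convention that is measure-zero on continuous data.

Transcription caveat: the primary reports for several minor indices are not
machine-readable; those registry entries are best-effort reconstructions
and say so in their `source` field. The registry is shipped as JSON
(`data/indices.json`) precisely so individual entries can be checked and
corrected without touching code; a registry round-trip reproduces identical
predictions by construction.

## Decision rules and the greedy tree

A `RuleSet` is an ordered list of conjunctive threshold paths
(`field ≤ t` / `field > t` → class). Validity — mutual exclusivity and
joint exhaustiveness — is *proved*, not assumed, by enumerating one probe
point per cell of the grid induced by the rule set's thresholds (each
threshold, all midpoints, one point beyond the maximum per field). The
shipped CRUISE rule set (six leaves on MCV 67.65/71.25, Hb 8.85/11.15,
MCHC 30.32) passes this audit: `{exclusive, exhaustive, leaf_count 6}`.

As printed, the CRUISE rules assign βTT to MCV > 71.25 fL. On clinically
realistic cohorts — where βTT sits at *lower* MCV — this published
orientation classifies inversely; we ship the rules as printed rather than
"correcting" them, and the synthetic-cohort tests therefore exercise the
rule engine, never the rule set's clinical accuracy.

The greedy fitter is a demonstrator, deliberately plain: exhaustive search
over midpoint thresholds of consecutive distinct sorted values, best
weighted Gini decrease, recursion until purity, `max_depth` (default 5),
`min_leaf` (default 1), or no strictly-positive decrease. Determinism is
part of the contract: ties break to the lexicographically lowest field
name, then the lowest threshold; leaf majorities tie to the
lexicographically smallest class. Because splits depend only on the induced
point partition, strictly increasing transforms of a predictor move the
thresholds but not the partition. Variable importance is summed
node-weighted impurity decrease per field, rescaled so the maximum is 100 %;
a single-leaf tree reports all zeros. It is *not* a reimplementation of
CART/CRUISE/QUEST/C5.0-class algorithms and makes no unbiased-selection
claims.

## Accuracy measures

βTT is the positive class. This is an inference, not a convention borrowed
blindly: with class sizes 708/470, the published F-measures are reproduced
from the published Youden/accuracy pairs only under that choice (e.g.
(668, 60, 40, 410) gives F = 93.04 % with βTT positive).

All thirteen measures follow the standard identities; DOR = +∞ when a
classifier makes no false negatives or no false positives (with non-zero
numerator), matching the "0 / ∞" NLR/DOR pattern of perfectly sensitive
indices. For a hard binary classifier the empirical AUC equals
(sens + spec)/2 = (J + 1)/2; the empirical ROC for continuous scores is the
threshold sweep whose area is the Mann-Whitney concordance probability with
ties counted ½ (verified against brute-force pairwise counting). AUC
standard errors use Hanley–McNeil; paired AUC differences use the DeLong
covariance of placement values (z and two-sided p; antisymmetric by
construction).

Confidence intervals (95 % default): Clopper–Pearson exact for the six
proportions; the standard log-method for PLR/NLR/DOR
(e.g. ln DOR ± z·√(1/tp + 1/fp + 1/fn + 1/tn)); and a stratified binomial
bootstrap (2000 resamples, seeded) for Youden/accuracy/F, for which no
closed convention exists. Degenerate cells yield one-sided bounds
(Clopper–Pearson handles 0 and n naturally) or flagged `nan` intervals —
never silently fabricated numbers. No claim is made that these CI recipes
match any particular published table's unstated method.

### Summary → confusion matrix reconstruction

With prevalence p = n₊/(n₊+n₋) and published J and A (percent),

    sens = (A − (1 − p)(1 + J)) / (2p − 1),   spec = (1 + J) − sens,

then tp = round(n₊·sens), tn = round(n₋·spec). At sizes in the hundreds
with n₊ ≠ n₋, a 2-decimal (J, A) pair determines (tp, tn) uniquely — the
package verifies the re-derived summary against the inputs and searches the
±1 integer neighbourhood to absorb rounding. The strict mode errors when no
integer matrix reproduces the inputs at 2 dp; a best-fit mode returns the
nearest matrix with its residuals, used for bulk table reconstruction where
a handful of published rows carry small internal rounding inconsistencies
(worst observed residual 0.015 percentage points).

## Method-similarity analysis

Profiles are the ten measures sensitivity, specificity, PPV, NPV, Youden,
accuracy, PLR, NLR, F-measure, AUC — DOR is excluded because it is the one
measure that is infinite for ordinary classifiers and is determined by
PLR/NLR regardless. Columns are z-standardized by default (population SD;
zero-variance columns map to zero) so the unbounded likelihood ratios
cannot dominate Euclidean distance; raw-scale distances remain available
for sensitivity analysis. Methods that are themselves degenerate (e.g. a
perfectly sensitive index has infinite PLR) can be handled by an explicit
percentile-capping rule; with capping disabled such entries are an error.

Embedding is classical (Torgerson) MDS: B = −½·J·D²·J, eigendecomposition,
coordinates from the top-k positive eigenvalues, axis signs fixed
deterministically. Exact Euclidean inputs of configuration rank ≤ k are
recovered to machine precision; the `strain` diagnostic reports the
eigenvalue mass outside the retained axes.

Clustering is complete linkage (scipy), whose merge heights are monotone;
cutting at height h bounds every cluster's diameter by h. The number of
groups is chosen by majority vote over five internal validity indices —
Calinski–Harabasz, silhouette, Dunn, Davies–Bouldin, C-index — each voting
for its optimal k among the candidate cuts (default 2..8), ties resolved to
the smallest k and near-ties flagged as weak evidence. This is a documented
subset standing in for large validity-index batteries; on genuinely
clustered profiles (three well-separated groups) the vote recovers k
decisively, but on homogeneous profile clouds hierarchical cutting must
still return some k ≥ 2 and the indices can legitimately scatter or prefer
many small clusters — the per-index score table is returned so that
situation is visible.

## Synthetic cohorts

Per group, the seven CBC variables are drawn from a correlated multivariate
normal over (hb, hct, mcv, mch, mchc, rbc, log rdw) — RDW on the log scale
for positivity and right skew — rejected against the inclusion box so the
requested group sizes are exact. HbA2 is truncated normal and ferritin
truncated log-normal, each consistent with its group's label rule by
construction, so zero emitted records violate their label. Values are
rounded to laboratory precision (0.1 units; RBC 0.01) and re-screened after
rounding. The cohort order is a seeded shuffle. Identical (config, model)
pairs give byte-identical CSVs.

Default group locations are literature-typical for the two conditions:

| variable | βTT mean (SD) | IDA mean (SD) |
|---|---|---|
| Hb g/dL | 10.5 (0.9) | 9.6 (1.0) |
| HCT % | 33.5 (2.8) | 31.5 (3.0) |
| MCV fL | 61.5 (4.0) | 72.5 (4.5) |
| MCH pg | 19.5 (1.4) | 21.8 (1.6) |
| MCHC g/dL | 31.2 (1.0) | 29.8 (1.1) |
| RBC 10¹²/L | 5.6 (0.65) | 4.35 (0.60) |
| RDW % | 14.5 (1.3) | 17.5 (2.0) |

βTT sits at lower MCV with a high red-cell count; IDA shows the wider RDW
and lower ferritin. The dispersions encode the field's experience that MCV
is the dominant single discriminator and HCT nearly uninformative: the
standardized group separation ranks mcv > rbc > rdw > mch > mchc > hb >
hct, and under the defaults the greedy tree's top importance variable is
MCV with HCT at zero, consistently across seeds. The `separation` knob
scales all seven mean differences about their midpoints: 0 removes the CBC
signal entirely (index AUCs ≈ 0.5), values above 1 exaggerate it; mean
index Youden increases monotonically in it. A Mann-Whitney per-variable
report (`check_group_separation`) is provided as a generator self-test.

What the synthetic data does *not* emulate: real measurement error
structure, analyser-specific rounding, the exact published descriptive
statistics, comorbidity-driven outliers, or any hemoglobinopathy beyond the
two classes. Passing pipeline tests on synthetic cohorts demonstrates the
machinery — filters, formulas, metrics, clustering — not clinical
performance claims; published-table reconstruction is the component that
touches real reported numbers.

## Problem sizes and numerical choices

The default analysis sizes are the reference composition (708/470); test
and script simulations use 200–500-patient cohorts and 10-seed repetitions,
which are ample for the structural properties they check. Bootstrap CIs use
2000 resamples. Tolerances: published-digit checks are exact at the printed
precision (2 dp percentages, 3 dp AUC); geometric identities (MDS recovery,
linkage-oracle agreement) at 1e-8; the reconstruction verifier accepts
residuals up to half the last printed digit (0.005 pp).

## Known limitations

- Several minor index formulas are reconstructions pending verification
  against their primary reports (flagged in the registry).
- The greedy tree is a demonstrator; no bias-corrected split selection.
- CI recipes are standard conventions, not a match to any specific
  published table's unstated method.
- The validity-index subset (5 indices) can select a different group count
  than large index batteries on weakly structured profiles; the vote tally
  and score table are always reported alongside the chosen k.
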