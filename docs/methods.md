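# Methods

## Classification model

The classifier is a dictionary-driven hierarchical string matcher, not a
statistical NLP model. Its behaviour is fully determined by three things:
the phrase dictionaries, the phrase priority (rank), and the section /
severity precedence rules.

**Normalization.** All matching happens on canonicalized text: lowercased,
punctuation replaced by spaces except hyphens between word characters,
whitespace collapsed. Normalization is idempotent, so pre-normalized input
is harmless. Matches are anchored at word boundaries, so a short station
token like "7" cannot fire inside "17"; the hierarchical substring case is
unaffected because a hyphen–letter transition is a word boundary (the
"small cell carcinoma" inside "non-small cell carcinoma" is still found,
and then suppressed by span consumption).

**Rank and span consumption.** Entries are scanned in rank order; by
default rank is descending phrase length with lexicographic tie-break, and
explicit integer ranks (small values) override all defaults. Each matched
span is consumed: a later (lower-priority) entry cannot match any
overlapping span. This single mechanism implements the category hierarchy:
"non-small cell carcinoma, favor adenocarcinoma" (mapped to
adenocarcinoma, the way such phrasing is read in practice) outranks
"non-small cell carcinoma", which outranks "small cell carcinoma";
"negative for malignant cells" (benign) outranks "malignant cells".
`validate_conflicts` reports every cross-category substring pair so a
dictionary author can confirm each is resolved by rank; with pure
length-default ranks this holds automatically.

**Section precedence.** Sections are read in report order: diagnosis,
consultation, then addenda chronologically. The latest section that yields
any category supplies the final call — amendments supersede the original
report. `changed_by_addendum` is set only when the diagnosis section
itself produced a category and a later section's winner differs; an
addendum that merely establishes a first classification, or restates the
original, is not counted as a change. Within one section, when several
categories match, the category whose group is highest in the severity
hierarchy (malignant > suspicious > insufficient > benign) wins; ties
within a group go to the earliest offset, which is deterministic and easy
to audit. A record with no match anywhere is *unclassified*; one with no
station match has station *UNKNOWN* (kept in cohort tables, excluded from
station crosstabs and regression).

**Packaged dictionaries.** The shipped diagnosis dictionary (15
categories, ~60 phrases) and station dictionary (24 IASLC/AJCC stations,
50 phrases) are synthetic representative stand-ins sized for testing; the
loader accepts any site-specific dictionary in the same TSV/YAML format.

## Rates, the GMR, and control limits

Provider comparisons use the **group median rate** (GMR): the median of
per-provider rates among providers above the volume threshold — not the
pooled rate, which a single high-volume provider could drag. With an even
provider count the median is the mean of the middle two. Thresholds:
`min_n = 250` specimens per provider and `min_station = 20` records per
station, chosen so that rates are estimated with reasonable precision and
regression levels are not over-fitted; both are configuration parameters.

Control limits are **exact binomial** quantile bounds under
X ~ Binomial(n, GMR): lower = max{k : P(X ≤ k−1) ≤ α/2}/n and
upper = min{k : P(X > k) ≤ α/2}/n. The normal approximation is avoided
deliberately: the outer bands (α = 10⁻⁶, 10⁻¹²) sit far in the tails where
it is badly wrong. Degenerate centers are handled exactly (GMR = 0 gives a
zero-width band at 0). The GMR is a fixed plug-in center: no uncertainty
is propagated from estimating the median, which matches standard
funnel-plot practice and keeps the limits interpretable as "range of a
conforming provider of this volume". Consequences verified by simulation:
under the null the flagged fraction at α = 0.05 is near (slightly below)
nominal, because flagging requires a count *strictly* outside the limit
count — a tie is in-control.

Two-sided provider p-values are 2·min(P(X ≤ k), P(X ≥ k)) capped at 1.

**Case-mix normalization.** Station mix differs across providers and
strongly predicts outcome (N1 nodes and 4L are harder to sample), so the
charts can display indirectly standardized rates: observed count divided
by the expected count (provider's per-station volumes × pooled per-station
rates), re-centered at the GMR. Stations lacking pooled data are dropped
from the expectation with a warning. Outlier flags always compare the raw
observed count with the binomial limits at the provider's own n; the
normalized rate orders and displays the points. Both raw and indirect
modes are available and reported.

## Regression

For each outcome (the four exclusive groups, plus selected carcinoma
categories) a logistic model with additive categorical factors SPS +
pathologist + station is fitted by maximum likelihood (Newton, BFGS
fallback). The reference level of each factor is its highest-volume level,
for stability. Per-factor significance uses likelihood-ratio tests (full
fit vs fit without the factor, df = levels − 1); LR was chosen over Wald
because it is better behaved with sparse cells, and the choice is recorded
in the output metadata. Non-convergence and a crude separation screen
(|coefficient| > 15) are flagged in the result rather than silently
accepted. ROC curves are computed in-sample by sweeping all unique
predicted probabilities, area by the trapezoid rule.

## Synthetic corpus generator

The generator defines the study conditions for every simulation-based
test. Defaults: 8,846 records, 13 stations with the subcarinal station
dominant (share 0.351) and the three largest stations carrying ~77% of
volume; per-station group probabilities follow the per-station profiles of
a large referral-center cohort (renormalized over the four groups);
7 SPS and 11 pathologists assigned uniformly (patients are assumed
randomly assigned to providers, i.i.d. records, no patient-level repeat
sampling and no temporal drift); category mixes within groups approximate
that cohort's composition. Provider effects are additive per-group
log-odds offsets entering a softmax over the four groups — for a single
group this is exactly an additive logistic effect, which is what the
regression module assumes and recovers. 20% of non-small-cell-carcinoma
records gain a refining addendum (≈79% to adenocarcinoma, 21% to squamous
cell carcinoma), emulating the dominant amendment pattern.

Rendering embeds a dictionary phrase of the true category in a template
sentence; distractor levels add prose (`mild`) or prose plus a negation
sentence in benign reports (`heavy`). Distractors are designed to exercise
the matcher's consumption and severity rules, not to defeat them; the
generator does **not** emulate ambiguous wording, descriptive-only
diagnoses, or pathological report formatting. Closed-loop recovery of
100% therefore validates the matching *algorithm*, not the accuracy of
any dictionary on real reports — on real data accuracy is bounded by
dictionary coverage and must be established by human audit
(`audit_sample` produces the seeded worksheet; `audit_summary` the
percent-categorized / percent-correct figures).

## Numerical and design choices

- Binomial CDF/SF via scipy; tests cross-check every limit against an
  independent full pmf-enumeration oracle for all n ≤ 200 across a p0 grid
  and all four alphas.
- Fractions are full precision internally; 3-decimal rounding only at
  display. Derived crosstab rows (insufficient + suspicious) are sums of
  fractions, so a displayed derived row equals the sum of the displayed
  fractions when those are exact at 3 decimals.
- Trimming is a single pass on input counts, not iterated to a fixed
  point; with the default thresholds the difference is immaterial and the
  single pass is easier to reason about.
- Text offsets are 0-based half-open into the normalized section text.
- Pipeline outputs are pure functions of config + seed; JSON is written
  with sorted keys so reruns are byte-identical (images excluded).
- Problem sizes used in the test-suite simulations: 10,000 records for
  classifier closure; 100 replicates of 11 × 800 records for chart power
  and calibration; 200 replicates of n = 5,000 for parameter recovery
  (bias of the mean estimated log-odds < 10% of the generating effect).

## Known limitations

- The matcher has no linguistic understanding: negation and refinement
  are handled only insofar as the dictionary encodes them as full phrases.
- Indirect standardization is one defensible normalization; other
  case-mix adjustments (direct standardization, model-based shrinkage)
  would give different normalized orderings.
- No multiple-testing correction across providers or groups: the bands
  are per-provider error statements, as is conventional for these charts.
- The regression ignores patient-level clustering (one record = one
  specimen) and fits no interactions; the generator is correspondingly
  additive, so interaction misspecification is untested.
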