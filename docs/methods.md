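# Methods

This note documents the models, conventions and design choices behind
taxid-eval, in the order the pipeline applies them.

## Scoring rubric

The rubric expresses taxonomic closeness of a suggestion to the
reference determination on a 100-point scale (see README for the full
table). Two choices deserve comment:

* **Subjective grades are annotations.** Grades such as "very close",
  "similar genus" or "good try" encode expert judgement that no
  name-matching algorithm can reproduce; they are read from the input
  data and validated against a closed, case-insensitive vocabulary —
  any other string is an error, never silently mapped. The package
  computes only the objective grades (species/genus/family match via a
  reference taxonomy, `classify_exact`); everything downstream of an
  annotation is exactly reproducible.
* **`good_try` is a printed range (10–20).** The default is the
  midpoint 15; it is configurable on `WeightScheme` within that range
  for sensitivity analyses.
* **`no_id`** (the tool returned nothing) scores 0 like `unknown` but is
  tracked separately because the wrong-family error rate excludes it
  from its denominator. In files it is encoded as a row with
  `position = 0`; in memory it is an empty suggestion run.

## Weighted score

The sequential update
`S_k = S_{k-1} + f_k · max(0, v(c_k, k) − S_{k-1})` with
`f = (0.50, 0.25, 0.13)` uses only upward differences, so the weighted
score never falls below the first-choice score, never exceeds 100, and
ignores suggestions beyond rank 4. Two conventions close gaps the
published rule leaves open:

* the position-dependent misleading values (−5/−4/−2) enter *through the
  same update*: a (misleading, misleading) record scores
  −5 + 0.5·(−4 − (−5)) = −4.5. An alternative reading (the whole record
  scores −4 outright) exists but is not implemented;
* misleading at rank 4 carries the rank-3 value −2. Being upward-only,
  this is inert unless the running score is below −2.
* the rank-4 fraction is 0.13 exactly as published, not 0.125.

Scores are kept as exact floats internally; all rounding (half-up,
integers for subset means, one decimal for averages and consistency) is
applied only in the formatting layer.

## Consistency over replicates

`I` = number of distinct families among the replicates' *first*
suggestions + 0.2 per extra distinct genus+species combination within a
family; each irrelevant replicate is its own singleton family;
`C = R − I`. Conventions:

* The first suggestion defines the replicate's "identified" family,
  matching the pairing of consistency with first-choice accuracy in the
  report tables.
* Irrelevant = `misleading`, `unknown`, `good_try` or no identification.
  A "good try" names a merely similar-looking plant, so its family
  carries no signal about what the tool believes the sample is.
* A "similar family" first choice counts under the *suggested* family's
  name, resolved through the taxonomy; unresolvable names key on the
  literal name so distinct names stay distinct.
* Two species of different genera within one family each add 0.2 (the
  count is of distinct genus+species combinations beyond the first).
* `C = R − I` generalizes the five-replicate design (`C = 5 − I`,
  range 0–4); `normalized_consistency` divides by `R − 1` for
  cross-design comparison.

Evaluation with missing replicates proceeds with a logged warning
(`strict=False`), never silent imputation — incomplete designs occur in
practice when individual app runs fail.

## Aggregation

The observation unit for tool comparison is the per-sample mean over
replicates (38 values per tool in the reference design, N = 9 × 38 = 342
for the omnibus test); accuracy/error percentages use all replicate-level
attempts (190 per tool). The overall average per tool equals the
sample-count-weighted mean of its subset means for any partition of the
samples — the suite asserts this identity, and `validate_partition`
refuses metadata whose subsets do not sum to the sample total.
"Wrong family or worse" is operationalized as first-choice category in
{good_try, unknown, misleading}: `similar_family` (40 points) is not
wrong.

## Statistics

* **Kruskal–Wallis** (tie-corrected, chi-square approximation) is
  delegated to `scipy.stats.kruskal` behind the module surface; fully
  tied inputs return (H = 0, p = 1). A hand-transcribed rank formula
  serves as the oracle in tests.
* **Post-hoc letters**: Dunn z tests on mean pooled ranks with the
  tie-corrected variance `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)`,
  two-sided p multiplied by k(k−1)/2 (capped at 1). The compact letter
  display uses insert-and-absorb, which guarantees that two groups share
  a letter **iff** their adjusted p ≥ α. The exact post-hoc used by
  commercial packages is not published; Dunn/Bonferroni is the
  documented choice here.
* **(n−1) chi-square** for two proportions: the Pearson statistic of the
  2×2 table times (N−1)/N, no continuity correction, 1 df; degenerate
  margins give (0, 1). Preferred over corrected chi-square for the
  small counts typical of per-tool proportions.
* **Kendall's W** with per-judge tie correction
  `W = 12S / (m²(n³−n) − mΣTᵢ)`, `χ² = m(n−1)W` on n−1 df. Judges are
  the sample subsets (plant parts and types), objects the tools.
* All p-values two-sided; α = 0.05 default, configurable.

## Synthetic data generator

The generator exists so that every stage — file formats, scoring,
consistency, aggregation, statistics — is testable end-to-end without
external data, and so that calibration claims (type-I error, parameter
recovery, ranking recovery) can be checked by simulation.

Each tool is a `ToolProfile`: a multinomial over first-choice match
categories, a law for the number of suggestions returned (1–4, given an
identification is returned), and a repeat probability ρ — each replicate
after the first repeats the previous answer verbatim with probability ρ,
else redraws. ρ is the minimal one-parameter model of the observed
phenomenon that replicates on the *same image* often disagree; it does
not model drift, learning or image-quality interactions. Concrete names
are realized from a synthetic taxonomy so that each drawn category is
true by construction (correct genus → a congeneric species, correct
family → a confamilial genus, and so on).

Defaults emulate the reference benchmark: 9 tools × 38 samples
(12 flowers, 3 fruits, 10 leaves, 13 whole plants) × 5 replicates. The
nine default profiles are derived from the published per-app headline
percentages (% = 100, % ≥ 80, % ≥ 50, %mad, %wrong) — band masses map
onto the corresponding rubric grades (the genus band split 70/15/15 over
correct-genus/small-genus/very-close, the family band 70/30 over
correct-family/similar-genus, the residual 30/70 over
good-try/unknown, with the no-id mass solved from the %wrong
denominator) — and ρ = C/4 from each app's published mean consistency.
The plant-type partition (16 herbs, 15 monocots, 7 woody) keeps the
published woody count and splits the remainder evenly; the published
type counts themselves contain a misprint (they sum to 55, not 38), so a
consistent partition was fixed once here. Randomness is counter-based
(per-(tool, sample) substreams spawned from the root seed), making runs
bit-for-bit reproducible and extension-stable.

What the generator does **not** emulate: image content and quality,
per-sample difficulty (all samples of a part/type are exchangeable),
confidence levels, app version drift, and correlations between tools on
the same sample. Passing tests therefore validate the *evaluation
machinery* under the design's sampling structure, not any claim about
real identification apps.

`recover_profile` inverts the generator: category frequencies over first
replicates estimate the multinomial, and
ρ̂ = (p_same − Σp̂²)/(1 − Σp̂²) corrects the adjacent-replicate
agreement rate for chance agreement (clipped to [0, 1]; for a degenerate
single-category profile repeats and redraws are indistinguishable).

## Problem sizes used in the checked examples

The suite runs the full 9 × 38 × 5 design throughout; simulation-based
calibration checks use 2 000 pipeline replicates for the null
letter-display property, 200 runs for Monte-Carlo convergence of the
accuracy bands, and 1 000–5 000 samples for parameter recovery — sizes
at which the 3-standard-error acceptance bands are decisive.

## Known limitations

* The rubric's subjective grades make cross-study comparability depend
  on annotator calibration; the package can only guarantee
  reproducibility downstream of the annotations.
* Dunn/Bonferroni is conservative; with nine tools the letter display
  will merge groups a less conservative post-hoc might separate.
* The chi-square approximations (Kruskal–Wallis, Kendall's W) are
  asymptotic; at very small group sizes exact permutation tests would be
  preferable and are out of scope.
* `classify_exact` requires both taxa in the reference taxonomy; synonym
  and vernacular-name resolution is deliberately left to the annotator.
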