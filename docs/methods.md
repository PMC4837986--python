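# Methods

This note documents the statistical procedures the package implements, the
conventions it fixes where the historical scoring descriptions were
ambiguous, what the synthetic fixtures do and do not emulate, and the
numerical choices that matter.

## Metrics

**Ranking metrics.** AUROC is computed as the Mann–Whitney statistic (the
fraction of positive/negative pairs ranked correctly, ties ½), via
scikit-learn's `roc_auc_score`; the test suite checks it against
exhaustive pair enumeration. AUPR uses the step-wise, non-interpolated
precision–recall area (`average_precision_score`): ranking by descending
confidence, tied scores grouped at a single threshold, area accumulated as
Σ (R_i − R_{i−1})·P_i. Both are invariant under strictly monotone
transforms of the scores; this is a tested property.

**Confusion metrics.** Matthews correlation returns 0 with a warning when
any denominator factor vanishes — the standard convention for degenerate
cohorts, chosen over raising so cohort sweeps do not crash. Balanced
accuracy requires at least one true positive-class and one true
negative-class example and errors otherwise.

**Concordance index.** A pair of records is *admissible* when the record
with the strictly earlier time is an observed event. Censored-vs-censored
pairs, pairs whose earlier time is censored, and tied-time pairs carry no
ordering information and are excluded (Harrell's rule; the test suite
cross-checks against lifelines on tie-free data). The caller declares the
risk orientation; the default treats larger predictions as riskier
(shorter expected survival). C is the fraction of admissible pairs ordered
correctly, risk ties counting ½.

**Probabilistic concordance (variant).** Real challenge outcomes are noisy
replicate averages, so a hard 0/1 vote per pair overstates certainty. In
the variant implemented here a pair with observed gap Δt ≥ 0 and
per-record noise sd_a, sd_b contributes Φ(Δt/√(sd_a²+sd_b²)) when the
prediction agrees with the observed ordering and one minus that when it
disagrees; risk ties contribute ½. Tied observed times are admissible when
at least one record is an event and contribute exactly ½ (Φ(0)) — total
uncertainty about the true ordering. As all sds → 0 the hard index is
recovered on tie-free times (tested at sd = 1e−9, tolerance 1e−6). This is
deliberately labeled a *variant*: the exact weighted wpc-index of the
drug-sensitivity challenges (pooled-variance estimation, per-drug
weighting) is specified only in external supplementary material and is out
of scope.

**Noise-normalized error.** E = Σ (X̂−X)²/(σ_b²+σ_s²X²) with defaults
σ_b = 0.1 (baseline, signal-independent noise) and σ_s = 0.2
(signal-dependent noise). When prediction error is actually drawn from
that variance model, each term is χ²₁ with unit mean — the analytic anchor
the fixture tests use. The time-course distance applies the same kernel
per retained time point, ignores the first `burn_in` points of each course
(the initial segment was given to participants), and divides by the total
retained count — 3 courses × 30 retained points = 1/90 in the canonical
configuration. The printed index bounds of the historical formula are
garbled in the source text; "courses × retained points with a 10-point
burn-in" is the reading consistent with the 1/90 normalization.

## Null models and p-values

Empirical p-values use add-one smoothing: p = (1 + c)/(N + 1) where c
counts null samples at least as extreme as the observation in the
*declared* tail direction. Consequences: p is never 0 (log-p combiners are
always defined), the smallest attainable p is 1/(N+1), and under a true
null p is uniform on {1/(N+1), …, 1} — calibration is verified by a
Kolmogorov–Smirnov test over 2000 replicates. Tail direction
(greater-is-better vs smaller-is-better) is an explicit attribute of every
null distribution, never inferred, because the corpus mixes both
orientations. z-scores use the sample standard deviation (N−1); the
convention is documented because the source formulas do not state it.

The assignment null (identity of 4 measured proteins among 7 candidate
species) is solved exactly by enumerating all 7·6·5·4 = 840 injective
assignments; P(all four correct) = 1/840, and the enumerator is checked
against 100k-draw Monte-Carlo within three standard errors. Enumeration is
capped at 2×10⁶ assignments; beyond that the error message points to the
Monte-Carlo fallback.

Every stochastic operation takes an explicit seed (ints or numpy
generators) and is reproducible bit-for-bit; there is no module-level RNG
state. Null samples can be exported/imported as a single-column CSV with a
two-line header (statistic name, tail) so published nulls can be replayed.

## Composite scores

All score formulas use base-10 logarithms. Some historical descriptions
print a bare "log"; a single base keeps every score on one scale and the
difference is a constant factor that does not affect ranking. The
pair-combiner −½ log₁₀(p_a·p_b) appears in two challenge families with
identical algebra and is implemented exactly once.

Two places need an extra convention:

* **Four-metric product score.** The printed formula −¼ ∏ p_j produces
  tiny negative values, unlike every sibling log-combiner; it is most
  likely a typo for a log form, but it is implemented literally, with an
  explicitly named `log_mode` flag providing the mean-neglog₁₀-p
  alternative. Nothing is silently "fixed".
* **Expression-prediction profiles.** Per-time-point and per-gene Spearman
  correlations each yield a two-sided association p-value; each family (8
  time profiles, 50 gene profiles in the canonical shape) is combined into
  a single p by Fisher's method, computed in log space so large statistics
  do not underflow. Whether the historical scorer combined per-profile
  p-values or pooled the profiles is not stated; Fisher's method is the
  standard combination for independent association tests and is the
  package's documented choice. Being two-sided, a perfectly anti-ranked
  submission scores as strongly as a perfect one — a property the tests
  assert rather than hide.

**Analytic p-value floor.** Closed-form p-values underflow to exactly 0 at
perfect correlation. Before entering a log they are clamped at 1e−300 —
the edge of the normal double range — rather than at some larger
pseudo-floor. The floor must be unreachable by any imperfect prediction:
a larger value (say 1e−16) would be hit already by very good submissions,
collapsing distinct qualities onto one score and destroying the
monotone-in-quality behaviour of the composite scorer. Empirical p-values
need no such floor; add-one smoothing bounds them at 1/(N+1).

Per-challenge orientation (is the final score greater-is-better or
smaller-is-better?) is declared once in the challenge descriptor and read
from there by aggregation and by the test harness, because the corpus
mixes orientations silently.

## Synthetic fixtures

The generators produce, from one seed, a gold standard and a prediction
whose fidelity is a single `quality` knob in [0, 1]: 1 reproduces the gold
exactly, 0 is uninformative noise, and the expected score of every scorer
improves monotonically in between. Two mixing schemes are used, chosen by
the nature of the gold standard:

* **Discrete gold (edge indicators, binary labels):** each item is
  *informative* with probability `quality` (its confidence equals the gold
  indicator) and uniform noise otherwise. A convex sum
  q·indicator + (1−q)·noise would separate the classes perfectly for every
  q ≥ ½ (AUROC ≡ 1), making all intermediate qualities indistinguishable;
  the mixture form keeps the ranking strictly graded while still giving
  AUROC exactly 1 at quality 1 and 0.5 in expectation at quality 0.
* **Continuous gold (time courses, tables, slopes, parameters, PWMs):**
  prediction = gold + (1−quality)·noise, with noise drawn from the
  scoring kernel's own variance model where one exists (time courses use
  σ_b, σ_s, so quality 0 has unit expected normalized error per retained
  point — an analytic anchor the acceptance harness checks).

Specifics worth knowing:

* **Networks**: directed, no self-loops; Erdős–Rényi edges are sampled
  uniformly without replacement; scale-free graphs grow by preferential
  attachment on in-degree (+1 smoothing) until the exact edge budget is
  hit. Defaults (50 nodes, 100 edges) mirror the classic in-silico
  setting. The heavier in-degree tail of the scale-free mode is a tested
  property.
* **Survival cohorts**: exponential event times with log-rate η ~ N(0,1),
  independent censoring at the stated rate (censoring time uniform before
  the event). The informative risk component is −log(observed time),
  standardized — a perfect-ranking oracle — mixed with standard normal
  noise; quality 1 therefore attains concordance exactly 1 even under
  censoring, which a risk built from η alone could not (the event time
  keeps exponential randomness around any covariate-based risk).
* **Assignments**: quality is the per-slot probability of keeping the
  correct identity; the remaining slots get random *incorrect* categories
  (injectivity preserved), so quality 0 means zero correct identities
  rather than a uniform draw.
* **PWMs**: gold matrices are uniform-column random PWMs; predictions are
  column-renormalized convex mixes with fresh random PWMs, so the
  Frobenius distance scales exactly linearly in (1−quality).

The fixtures emulate only the statistical shape the scoring procedures
consume — label imbalance, censoring, heteroscedastic noise, rank
structure. They do not emulate the biological content of any real data
set (expression compendia, genotypes, clinical covariates), so passing
tests certify the *scoring machinery*, not biological recoverability.

## Bundled challenges and problem sizes

Ten challenge families ship end-to-end: binary target identification,
signaling-cascade assignment, signaling response (E + empirical p, two
sub-challenges), expression-prediction rank profiles, five-network
inference, PWM families (kinase/PDZ/SH3 with 3/4/3 matrices), parameter +
time-course estimation, survival concordance, and slope RMSE. Each bundles
deterministic synthetic gold standards, template providers (a deliberately
mediocre quality-0.3 example submission), and seeded empirical nulls;
every other historical nickname is registered with metadata and a pointer
to the library functions implementing its metric (or its
unreleased/no-gold/external status).

The bundled configurations are deliberately small — e.g. 5-node networks,
4×2 PWMs, 5-point response vectors, 20–80-item binary cohorts, nulls of
100–200 samples. Besides keeping the full suite fast on one CPU, the sizes
are chosen so that each empirical null has broad relative spread: a
p-value-based final score saturates at its 1/(N+1) floor once a submission
beats every null sample, and with large, concentrated statistics every
decent submission would sit on the floor, collapsing distinct qualities
onto one value. At these scales the floor is reached routinely only by
(near-)perfect submissions, so the expected final score remains strictly
increasing across the whole quality grid — verified by the acceptance
harness at qualities {0, 0.25, 0.5, 0.75, 1}. Library functions accept
arbitrary sizes; nothing in the scoring code depends on the bundled toys.

The "self-scoring optimality" check is dominance, not strict victory: the
gold standard scored as its own submission must be at least as good as
every random submission. Strictness is impossible for p-value-final
scorers — a random submission lands on the same floor as the gold with
probability 1/(N+1) per draw — and dominance is the property that matters.

## Degenerate inputs and tie-breaking

Ranking metrics refuse single-class label vectors, correlations refuse
zero-variance vectors, the concordance index refuses cohorts with no
admissible pair, Jaccard refuses two empty sets — all with messages naming
the offending condition. File readers validate on load and carry the file
position (line, block, column) in every error; near-miss PWM columns
(sum within 1e−3 of 1) are renormalized with a warning, worse columns are
errors. Ties: ½ per pair in ranking and concordance metrics, average ranks
in Spearman and in rank aggregation, tied confidences grouped at one
threshold in AUPR, ties in edge lists keeping file order after the stable
descending sort.

## Known limitations

* The exact wpc-index and the integrated-AUC definition live in external
  supplements/packages; only the documented probabilistic-concordance
  variant is provided, and it is labeled as such wherever it is wired in.
* Alignment-based transcript scoring and the whole-cell external scorer
  are out of scope; the registry marks them.
* Scores that rank a submission against a cohort of other participants
  (mean-rank finals) are functions of the cohort; the library provides the
  aggregation operators and accepts any user-supplied cohort, but no
  historical cohort data ships with the package, so published leaderboard
  numbers are not reproduced.
* The registry's bundled gold standards are synthetic; scoring real
  historical submissions requires supplying the corresponding real gold
  standards through the file-based hooks where available.
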