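# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations of `taskstruct`.

## Task designs

Each experiment crosses two binary stimulus dimensions into four categories
(Experiment 1: border color red/blue × shape square/circle around
task-irrelevant object images; Experiments 2–4: face age young/old × gender
female/male) and assigns categories to key positions 1–4 (physical keys
v, b, n, m under the right hand).  The canonical *clustered* mapping nests
the sub-dimension at adjacent keys within each level of the biased
(candidate supraordinate) dimension — positions (1, 2) and (3, 4) — while
the canonical *non-clustered* mapping splits each biased level's pair
across non-adjacent keys (1, 4) and (3, 2), following the published
instruction patterns.  Other non-adjacent bijections can be constructed
directly through `ResponseMapping`.

Key distance is the absolute difference of integer key positions.  The
clustered mapping's four same-feature-level pairs sit at distances
(1, 1, 2, 2), mean 1.5 keyboard units; our canonical non-clustered pattern
gives (3, 1, 2, 2), mean 2.0.  (A published distance list for non-clustered
mappings containing a "4" is not reproducible from any bijection of four
adjacent keys, whose maximum distance is 3; we treat it as a typo and do
not attempt to match it.)

Learning phases have 128 (Experiment 1) or 120 (Experiments 2–4) trials,
each category appearing exactly n/4 times in seeded random order with
trial-unique image ids.  Memory phases contain every learning image plus
the smallest category-balanced number of new images at least one third of
the old count — reproducing 128 + 44 = 172 and 120 + 40 = 160 trials.
Counterbalancing yields 8 versions for Experiment 1 (cluster group ×
biased dimension × source-question order) and 4 for Experiments 2–4.
Experiment 3 switches the mapping halfway (after trial 60) by rebuilding
the same pattern around the other dimension; for both cluster groups this
preserves exactly two category–key pairs (positive transfer) and changes
two (negative transfer).  The face stimulus catalog is reconstructed as
synthetic metadata (208 entries, 52 per category: 43 white plus 9 of other
racial backgrounds); no images are handled.

## Generative agent model

The simulator produces the statistical structure the analysis assumes,
not a mechanistic cognitive model (no latent-cause inference, no
reinforcement learning, no parameter fitting to human data).

* **Accuracy.** p(correct at trial t) = p∞ − (p∞ − 0.25)·exp(−t/τ), the
  simplest saturating curve from 4-choice chance.  Defaults: p∞ = 0.92,
  τ = 6 trials (the curve clears typical learning criteria roughly fifteen
  trials in), lapse rate 0.02 (uniform random key).  In Experiment 3,
  negative-transfer categories restart their curve at the rule switch;
  positive-transfer categories continue.  Errors pick uniformly among the
  three wrong keys.
* **Reaction times.** Lognormal with median 650 ms and log-SD 0.2
  (right-skewed, positive support; the literature's standard RT
  phenomenology — no RT magnitudes were available to fit).  Hierarchical
  agents add Δ ms (default 80) on the natural scale whenever their
  supraordinate dimension's level changes between trials; flat agents have
  Δ = 0 by construction.  An optional distinct post-rule-switch Δ supports
  Experiment-3 analyses.  Sampled RTs beyond the 1250 ms response window
  become timeouts, and responses additionally time out at a base rate of
  0.03 (matching the ~3% observed timeout rates).
* **Recognition memory.** Equal-variance Gaussian signal detection: new
  items N(0, 1); old items N(s_b, 1) where s_b depends on the
  learning-phase bin of encoding.  Defaults s = (1.0, 0.8, 0.65, 0.55)
  with rating criteria (−0.5, 0.5, 1.5), giving false-alarm ≈ 0.31 and hit
  rates ≈ 0.69/0.62/0.56/0.52 by bin — magnitudes comparable to observed
  face-memory data, with a primacy decline.  The middle criterion is the
  old/new decision point after collapsing the four ratings.  Cohorts
  emulating the early-encoding cost reduce clustered agents' bin-1 strength
  by 0.25 d' units, back-derived from published early-bin hit rates
  (≈ 0.57 vs 0.65).  Source-memory responses (Experiment 1) are correct
  with probability 0.5 by default — chance, matching the null source-memory
  findings.
* **Cohorts.** Each group is a mixture over agent configurations; defaults
  put 40% hierarchical agents in the clustered group and 5% in the
  non-clustered group (mirroring observed flagged-individual proportions),
  split evenly between the two candidate supraordinate dimensions.
  Versions are assigned round-robin within group.  Per-participant random
  streams are spawned deterministically from the master seed.

What passing tests on these agents do **not** show: robustness to RT
distributions with condition-dependent variance, sequential dependencies
(post-error slowing, fatigue), response biases in the memory test, or any
relation between a human's switch cost and their true strategy — the
simulator implements the very assumptions the analysis makes, so these
tests establish internal consistency and calibration, not validity for
arbitrary real data.

## Preprocessing conventions

RT analyses keep correct, responded trials with 200 ≤ RT ≤ 1250 ms;
accuracy analyses keep all responded trials (errors are the outcome); both
exclude trial 1.  The printed inequalities are read strictly, so boundary
values (200, 1250 ms; 65.0% accuracy) are retained/included.  Memory
analyses keep responded trials with RT ≥ 200 ms.  Transitions are labeled
under a candidate supraordinate dimension: repeats (including exact
category repetitions — the supraordinate rule persists) vs switches, with
double feature switches excluded as unattributable.  In Experiment 3 each
half is labeled independently (the post-switch half's first trial has no
within-half predecessor); only trial 1 of the session is excluded as
"first", not trial 61.  Bins are (30, 30, 30, 38) for 128 trials and
4 × 30 for 120; participants need ≥ 10 responded old trials per bin to
enter binned ANOVAs.  Accuracy below 65% or a failed post-test excludes a
participant.

## Switch-cost inference

Signed cost: μ_switch − μ_repeat for RT, acc_repeat − acc_switch for
accuracy, so positive always reads as structure evidence.  The normalized
cost divides by sqrt(½(σ_S² + σ_N²)) — per-condition SDs for
individual-level tests (each participant against their own null), SEMs for
the group-level z form (participants treated as having similar variance).
Inference uses the absolute normalized cost, since its sign only encodes
which dimension is supraordinate.

The null distribution shuffles the repeat/switch labels over the included
trials (after all filters; condition counts preserved) and recomputes the
absolute statistic — 10,000 times by default.  Group-level nulls average
the k-th permuted statistic across participants, with independent
per-participant streams.  A result is flagged when the observed value
exceeds at least 97.5% of its null (two-sided 2.5% criterion, upper tail
only; raw percentiles are reported so lower-tail readings remain
recoverable).  Percentiles use the mid-rank convention (ties counted half),
which equals the strictly-below fraction for continuous RT data and keeps
the accuracy-measure test calibrated despite its discrete null; the
strictly-below percentile is also exposed.  A permutation draw with zero
pooled spread contributes a 0 statistic and is logged.  Conditions with
fewer than two trials make the cost undefined; such participants are
dropped from the affected analysis with a log entry.

The labeling used for testing is fixed a priori at the design's biased
dimension — selecting the participant-maximizing dimension first would
inflate the false-positive rate.  Which dimension a participant actually
used is inferred separately, as the dimension whose labeling yields the
larger signed RT cost; exact ties fall back to the mapping's biased
dimension (clustered) or the lexicographically first name, and are logged.
The "structure former" flag is the union of the RT and accuracy flags, with
a ~1 − 0.975² ≈ 4.9% nominal false-positive rate under independence.

## Memory statistics

Ratings collapse to old/new; hit and false-alarm rates are computed per
participant, with above-chance encoding tested by paired t (hit vs FA).
The baseline memory probe uses the one category whose key assignment is
shared across learner groups in every counterbalanced version (the
category at the first level of both dimensions under the canonical
patterns).

The binned hit-rate ANOVA is a split-plot design: bin within, learner
group (and experiment, when pooling) between, optional centered continuous
covariates (individual RT and accuracy switch costs) with
covariate-by-bin interactions.  The engine computes type-III-style sums of
squares by model comparison with sum-coded factors; the within stratum is
fit on deviations from participant means with error degrees of freedom
(b − 1)(N − g − c).  Greenhouse–Geisser ε comes from the pooled
within-group covariance (the mixed-design convention) and corrects within
effects whenever the within factor has more than two levels; ε is reported
always.  The engine is validated to 6 decimals against an independent
reference implementation on fixed toy tables.  Covariates are centered
before entry to preserve main-effect interpretability.

Designs with two 2-level within factors (source memory: question type ×
rating; transfer: transfer type × post-switch time bin) are analyzed by
the exact contrast method: each within effect is a per-participant
contrast score tested as the sum-coded intercept, its group interaction as
the group term, both with error df N − g.  Effect sizes: d_z = t/√n with
CL = Φ(d_z) for paired/one-sample tests, pooled-SD d_s with CL = Φ(d_s/√2)
for independent tests, partial η² for ANOVA effects.  These conventions
are fixed and documented rather than tuned to any published d/CL pair,
as published pairs are not mutually consistent across experiments.  The
source-memory analysis is restricted to old images, mirroring the original
analysis scope.

## Problem sizes and runtime choices

The validation studies use 1,000 flat agents × 2,000 permutations for
flag calibration, 1,000 hierarchical agents for Δ = 80 ms and dimension
recovery, and 200 replicate 60-participant cohorts for the early-memory
replication rate; the permutation null is fully vectorized (a shuffle
matrix per participant), so the whole acceptance run completes in a few
minutes on one CPU.  Exact-null enumeration (all C(n, n_S) label splits)
is used as an oracle for ≤ 8-trial problems.

## Known limitations

* The agent model is phenomenological; it cannot distinguish competing
  cognitive accounts of *why* structure formation taxes encoding.
* Group-level percentile calibration assumes participants' trial counts
  are comparable; strongly unequal counts change each participant's weight
  in the averaged null.
* The split-plot engine supports one within factor with arbitrary levels
  plus at most two crossed between factors; the 2×2-within designs use the
  contrast method instead (exact for 2-level factors).
* Exclusion gates based on the post-test questionnaire are modeled only as
  a boolean input; no questionnaire content is simulated.
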