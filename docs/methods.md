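# Methods

`valuedyn` studies how the expected value of a reward-predicting cue is
maintained across a ~2.4 s delay by a population of cortical neurons, and
how seemingly contradictory descriptions of that maintenance — a stable,
persistent code versus a dynamic, temporally local one — can both be
extracted from the same population with targeted methods. Because the
package is exercised entirely on synthetic data, every analysis can be
validated against known ground truth.

## Task and synthetic sessions

A trial presents a reward-predicting cue (value 1–4, reward type juice or
bar) at t = 0 s, removes it at 0.6 s, shows a response-instruction cue at
2.1 s (a joystick sub-task that interrupts the delay) and delivers reward
at 3.0 s. The delay proper runs from cue offset to reward.

Units fire as inhomogeneous Poisson processes (thinning sampler) whose
rate functions implement one of seven coding regimes: stable linear value
coding (baseline + gain × centered value, cue to reward), non-monotonic
value tuning (an arbitrary per-value rate vector), sequential coding (a
Gaussian bump whose amplitude is value-modulated; bump centers tile the
cue→reward interval), sign-reversing value coding, reward-type coding,
pure time ramps, and untuned baseline firing. Rates are clipped at zero.
Event times are identical across trials (jitter is deliberately off so
that epoch alignment is exact in tests).

Default parameter ranges (uniform draws) are the study conditions of all
shipped experiments: baselines 2–8 Hz (low cortical range; variations stay
above the 1 Hz exclusion so the unit count is stable), stable value gain
0.5–1.0 Hz per value step, sequential bump amplitude 8–14 Hz with value
gain 3–6 Hz/step and SD 0.15–0.3 s. The ratio of persistent to transient
signal is the load-bearing choice: it plants a population whose *raw*
code is dominated by strong dynamic activity riding on a weaker persistent
value signal, the regime the extraction methods are designed for. With
persistent gains much larger, plain cross-temporal decoding would already
be significant at every delay time-pair and there would be nothing for
the subspace/ensemble machinery to reveal. Sessions carry 50 trials per
condition (4 values × 2 types) so that pseudo-population draws of 40 per
condition remain genuinely random.

What the generator does *not* emulate: trial-to-trial rate correlations
(noise correlations), non-Poisson spiking statistics, event-time jitter,
session-to-session drift, and mixed selectivity beyond the listed classes.
Passing tests therefore demonstrate that the analysis machinery recovers
what was planted under independent Poisson noise, not that real cortical
data contain such codes.

## Rate estimation and binning

Spike trains are convolved with a unit-area Gaussian kernel (SD 100 ms;
50 ms for the trajectory-speed and time-regression analyses, which need
finer temporal resolution). Smoothing runs over the padded simulation
window before epoching, so pre-cue bins can legitimately contain post-cue
information — this is a property of the method, documented rather than
"fixed". The smoothed rate is divided into three epochs locked to cue
onset ([−0.5, +1.3] s), the response cue ([−0.8, +0.45] s) and reward
([−0.45, +0.5] s); the extents are chosen so the epochs abut without
overlap for the default timing and are configurable. Bins are 100 ms
wide, stepped every 25 ms for encoding and 50 ms for decoding, with one
bin per step-start inside the epoch (40 and 20 bins per second of
activity respectively; the last bins may overhang the epoch end by
bin_width − step, which the padded rate grid covers). A bin's value is
the mean smoothed rate inside the half-open bin interval. Units whose
session-wide mean rate is below 1 Hz are excluded (exactly 1 Hz is kept).

Pseudo-populations draw, per unit and condition, a fixed number of trials
without replacement (40 per condition by default) and concatenate units
recorded in different sessions as if simultaneous. The draw is repeated
five times; every population-level statistic is reported as the mean over
the five datasets, and significance is aggregated across them.

## Unit encoding

Each unit's rate in each bin is fit with a two-factor linear model
(categorical value × reward type with interaction) and per-bin F tests.
The design is balanced by construction, so the vectorized sums-of-squares
decomposition equals type-II/III ANOVA (cross-checked against statsmodels
in the tests). A bin encodes a variable only when it sits inside a run of
at least 7 consecutive bins with p < 0.01 (~175 ms at the 25 ms step).
With ~160 overlapping, kernel-correlated bins per unit this rule cannot
push the unit-level false-positive rate below the per-bin alpha, but it is
far more conservative than accepting a unit on any single significant bin
(measured on untuned units: ~0.1 versus ~0.95), and it excludes isolated
significant bins entirely. Latency is the first bin of the first
qualifying run.

Delay summary measures (delay = cue offset → reward):

* encoding strength `es = mean_t(−log10 p(t))` (the log base follows the
  convention that −log p between 2 and 5 spans p from 0.01 to 1e−5);
* encoding duration: fraction of delay bins significant under the run rule;
* stability `S = avg_{v≠w} |(1/T) Σ_t tanh(10 (x̄_v(t) − x̄_w(t)) / sp_vw(t))|`
  with `sp_vw = sqrt((s_v² + s_w²)/2)`. The pooled SD is computed per bin
  (the natural reading; the defining formula does not index it by time).
  S lives in [0, 1]: persistent separations saturate tanh toward 1, sign
  reversals cancel in the time sum toward 0. Note S is a time *sum*, so it
  is invariant to bin order; it measures the sign history, not temporal
  smoothness. Degenerate bins (zero pooled SD) contribute ±1 for a nonzero
  mean difference and 0 otherwise, and are flagged;
* d′: |mean difference| / pooled SD of per-trial rates averaged over cue
  onset → reward (the averaging window is a package choice; no canonical
  window exists), averaged over the six value pairs; zero-SD pairs are
  excluded.

The split-half analysis splits trials stratified by condition, applies
the full per-bin/run-rule pipeline to each half over the delay, keeps
units significant in both halves, and Spearman-correlates peak-encoding
bins and durations across halves. Non-linear value coders are units
significant for categorical value but not for the value × type interaction
and not for a numeric-value regression slope, all under the same run rule.
Region comparisons use per-bin 2×2 chi-square tests on encoding
proportions (skipped when an expected cell is below 1), an overall
any-time-encoding chi-square, and Kruskal–Wallis on latencies.

## Decoding

The classifier is ridge regression on ±1 targets, one per unordered value
pair (one-versus-one; 4 classes → 6 classifiers), predicting by majority
vote. Vote ties are broken by the summed signed margins toward each
candidate class, then by the lowest class index — deterministic by
construction. Features are per-unit rates at a single bin, z-scored with
training-fold statistics (one mean/SD per unit, pooled over bins, so a
readout trained at one time is applicable at another); without this,
high-rate units dominate the L2 penalty. The intercept is fit on centered
data per pair.

The penalty λ is picked from the 15-value grid 10^−2 … 10^5 (half-decade
steps) by inner 4-fold cross-validation on the first outer fold's training
trials, maximizing same-time accuracy averaged over cue→reward bins; ties
go to the smallest λ. One λ* serves the whole dataset (the defining
protocol uses a single λ per population; the number of inner folds is a
package choice). The SVD of each training block is computed once and
reused across the grid.

Cross-temporal decoding trains at bin t1 and tests at every bin t2 under
stratified 5-fold CV; test trials are always out of sample, including on
the diagonal, and the diagonal *is* standard decoding — the same code path
runs both, so their equality is exact, not approximate. Significance:
labels are shuffled (1000 times at full scale; 100 in the shipped
desk-scale runs), the full CV pipeline is re-run per shuffle with the same
fold partition and λ, and p = #(shuffled accuracy > observed)/n_perm,
with p = 0 meaning "below 1/n_perm". Across the five datasets p-values
are aggregated as min(1, 2 × mean p) — valid under arbitrary dependence —
and thresholded at 0.01.

## Value subspace

Rates are averaged cue onset → reward and across trials per value class,
giving a 4 × n_units matrix; PCA of this matrix (columns centered) yields
three components (four classes minus one). Any single-bin population
vector projects into this subspace, which captures value variance while
discarding temporal structure. A unit's unsigned weight is the L2 norm of
its loadings across the three components.

Decoding in the subspace uses split/swap nested CV: within each outer
training fold, half the trials define the subspace, the other half trains
the ridge decoder, the roles are swapped, and the two accuracy matrices
(evaluated on the untouched outer test fold) are averaged. The subspace
never sees decoder-test trials; a deliberate-leak mode (test-only) shows
the inflation this prevents on pure-noise data. Subspace permutation
tests shuffle training labels only, so the null preserves the subspace
machinery's propensity to structure noise.

## Ensembles

Greedy backward elimination: starting from the full population, remove at
each step the unit whose removal maximizes the objective (ties → lowest
position), down to one unit; the selected ensemble is the argmax over the
trace (first occurrence, i.e. the largest such ensemble), so its score is
never below the full population's. Two objectives:

* stability: mean CTD accuracy over all train/test pairs in cue→reward.
  For the combined stable pipeline each candidate ensemble is evaluated
  through the subspace projection (subspace and decoder fit on one half of
  the search trials, accuracy measured on the other half, swapped and
  averaged — a two-run simplification of the full split/swap used for
  final evaluation, chosen for search cost);
* locality: for each training bin, a Gaussian `a·exp(−(t−μ)²/2σ²) + b` is
  fit to accuracy versus testing time with b fixed at chance (0.25) and μ
  at the training time; only a ≥ 0 and σ are free. The locality measure is
  the mean over training bins of (fitted peak − 0.25)/σ̂. The fit is
  profile least squares: a has a closed form given σ, and the 1-D σ
  problem is solved by golden-section search on [half a test-bin step,
  the full testing span] (60 iterations, deterministic); a failed bin
  contributes 0 and is flagged. An independent dense (a, σ) grid search
  is kept as the oracle.

Search grids follow the cost-saving convention of coarse search, fine
report: the stable search uses non-overlapping 200 ms bins; the dynamic
search trains on one in five delay bins while testing on every bin.
Searches are nested: they run on outer-fold training trials and selected
ensembles are evaluated on held-out trials. The desk-scale runs use one
search instance per dataset (5 instances total) rather than 5 × 5; this,
the 100-permutation tests, the 200 ms significance grid and the 100 ms
"fine" grid for the dynamic analyses are the package's problem sizes for
the shipped experiments, all configurable upward.

Per-unit contributions: the change in the objective when the unit was
removed during the search (the last removal is discarded — NaN — as is
the single never-removed unit), or leave-one-out deltas for a fixed
ensemble. For display and sign-split correlations the symmetric square
root `ac = sign(x)√|x|` is applied; it is monotone, so rank statistics
are unchanged. Ensemble overlap between paired stable/dynamic instances
uses a 2×2 chi-square of joint membership with Benjamini–Hochberg
correction across instances at 0.01; degenerate margins are skipped.

The batched implementations used by the greedy search are exact, not
approximate: dropping one unit from a ridge solution follows a
block-inverse downdate of the Gram matrix, and dropping one column from
the 4 × n class-mean matrix needs one small SVD per candidate; contract
tests assert bit-level agreement with the naive per-candidate refits.

## Population dynamics and correlations

Trajectory speed is the Euclidean distance between successive time-bin
vectors of the trial-averaged population activity (50 ms kernel); steps
crossing epoch junctions are NaN; its scale grows with unit count by
design. Time regression predicts the integer bin index from the
population vector by OLS with leave-one-trial-out CV, implemented with
the exact grouped-residual identity (verified against explicit refits);
rank-deficient fits fall back to a tiny ridge and are flagged. The
encoding↔decoding correlation battery reports Spearman R between unit
measures (es, duration, S) and contributions (unsigned subspace weights,
ensemble accuracy contributions — the latter split by sign, since their
distribution is asymmetric around zero); strata with fewer than 3 units
are reported as undefined.

## Numerical and degenerate-input conventions

p-values are clipped to the machine floor before logs (flagged);
zero-variance ANOVA bins get p = 1 (flagged); zero pooled SD follows the
sign convention above; stratified folds/halves guarantee class balance
and raise if a class is absent; OVO tie-breaking and greedy tie-breaking
are lowest-index; permutation p = 0 is stored as 0 and read as
"< 1/n_perm". All randomness flows through named NumPy SeedSequences and
is logged in result metadata; identical seeds reproduce byte-identical
outputs.

## Known limitations

Greedy backward elimination does not guarantee globally optimal
ensembles (checked against exhaustive search only at 8 units). The
single-λ* protocol shares one hyperparameter across outer folds, a mild
deviation from fully nested tuning. The simplified two-run search
objective for the combined pipeline trades a little statistical purity
(subspace and decoder share search-half trials; the held-out evaluation
remains clean) for an order-of-magnitude search speedup. The synthetic
noise model is independent Poisson; correlated-noise effects on subspace
and ensemble selection are untested.
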