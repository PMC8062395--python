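# Methods

## Deviations and the reference median

Every analysis consumes the signed deviation of one annotator's boundary
time from the median time for that (token, boundary), pooled across all
annotators **and both modalities**.  Pooling both modalities gives the two
modalities a common reference, so a modality difference appears as a
difference in deviation spread, not as a shifted reference.  Even-sized
groups use the mean-of-central-values median; singleton groups are legal
and deviate by zero.  Medians are computed once, globally;
per-subset recomputation is not performed (each subset of the proportion
design reuses the global references), keeping subsets comparable.
Deviations are per annotation record, never per annotator average.  No
outlier trimming or per-annotator bias correction is applied.

## Classic coefficients

- **Krippendorff's alpha**, interval metric: α = 1 − D_o/D_e with
  δ(v,v′) = (v−v′)².  Observed disagreement sums within-unit ordered pairs,
  each unit normalized by (m_u − 1); expected disagreement pairs all
  pairable values.  Units with fewer than two ratings are excluded.  A
  matrix whose pairable values are all identical has undefined alpha and
  raises rather than returning a number.
- **ICC(1,1)**, one-way random effects: (MSB − MSW)/(MSB + (k₀−1)MSW) with
  the standard unbalanced effective group size
  k₀ = (N − Σk_u²/N)/(n−1).  The one-way form is the right one here
  because each token is rated by whichever annotators happened to see it;
  two-way (rater-crossed) forms are out of scope.
- **% within tolerance** uses an inclusive comparison (|d| ≤ tol); the
  convention is fixed for determinism.

The **sensitivity sweep** rebuilds times as `median + λ·deviation + ε`,
ε ~ N(0, sd²): λ < 1 removes annotation noise, λ > 1 adds it, and the
additive term models clock-level jitter.  This λ/sd parametrization is
this package's choice of tweak mechanism.  On data whose
between-unit spread dwarfs the within-unit error — as real boundary data
always are, since words occur at widely different trial times — alpha and
the ICC are invariant to λ to within ~1e−9 while the mixture statistic
scales roughly linearly with λ.  That contrast is asserted as a property
test rather than against any published table.

## The mixture reliability statistic

The deviation distribution has a tall narrow peak and broad tails and is
centered at zero, which motivates a zero-mean three-Gaussian mixture with
component roles *narrow* (σ ∈ [0.0001, 2] ms), *medium* ([1.5, 8] ms) and
*wide* ([2.5, 40] ms).  The bounds deliberately overlap so the fit stays
data-driven, and no anti-label-switching penalty is applied.  All means
are clamped at 0; θ lives on the simplex.  The summary statistic is
Σθᵢσᵢ (ms).

**KL objective.**  Observed and model distributions are discretized on a
shared grid, by default 1-ms bins over [−50, +50] ms — covering the widest
permitted σ beyond one standard deviation and the typical plotting range.
Model bin mass comes from CDF differences; both histograms are floored at
ε = 1e−9 and renormalized, which both keeps the divergences finite and
conditions the model on the support.  Observed values outside the support
are clipped into the edge bins so every record keeps its mass; a sample
entirely outside the support is an error.  The objective is the mean of
the two directed divergences, in nats.  The binning is a config object
because no single discretization is canonical; narrower bins (0.5 ms) are
appropriate when σ_narrow may fall below 1 ms, while much wider supports
make the histogram sparse and degrade the fit.

**Optimizer.**  A global-best particle swarm over six raw dimensions:
three component weights in [0,1] (normalized to θ by their sum; a
degenerate sum < 1e−6 re-initializes the particle) plus the three sigmas.
Hyperparameters are the standard constriction values (inertia 0.7298,
cognitive = social = 1.49618), velocity clamped to half the per-dimension
range, positions clamped to the box, 60 particles for at most 2000
iterations, early-stopping when the global best improves by < 1e−9 for
200 consecutive iterations (in practice fits converge within ~300
iterations).  The swarm is fully vectorized over particles, so a fit
takes ~0.1 s.  The entire final swarm is returned because the downstream
regression uses every particle; the recorded per-particle KL values index
the final swarm, while the summary statistic uses the historical global
best.

**Known bias.**  The binned-KL criterion slightly underweights the sparse
far tail, so σ_wide (and hence the weighted sigma) is recovered a little
low — typically 10–15% at n = 3600.  This is a property of the
histogram-KL method itself, shared by any implementation of it; parameter
recovery is therefore validated with a 20% relative-error budget (median
over seeds).

## Proportion subsets and regression

Rate compositions are all splits of 10 tenths over (fast, medium, slow)
with each share in 1..8 tenths (36 compositions), crossed with manual
proportions 0.2..0.8 in steps of 0.1 — 252 cells, enumerated in a fixed
deterministic order.  A subset of a given size is drawn by
largest-remainder allocation of the joint (modality × rate) fractions,
without replacement within strata, so the marginal counts match the cell
within rounding.  The subset size is a required parameter (600 by default
in the CLI, i.e. one balanced-cell multiple); per-subset seeds derive from
the master seed via a `SeedSequence([master, index])` counter so partial
re-runs are reproducible.

The regression is weighted least squares of per-particle component sigmas
on {intercept, p_ponss, p_fast, p_slow, two sum-to-zero component
contrasts, and all linear × contrast interactions}.  The manual and
medium proportions are excluded as exact linear functions of the included
predictors.  Weights are θ_component × (1 − KL), clamped at zero since a
negative weight is meaningless in WLS.  A Bayesian distributional backend
(Student-t likelihood with component-predicted scale) would be a drop-in
replacement at the `sigma_regression` seam; the WLS form keeps the same
fixed-effect design and makes the effect estimates the comparable
quantity without a sampler dependency.

## Efficiency bootstrap

Baseline cost per word: each trial event's duration divided by the
trial's good-word count, attributed per annotator event.  Trials with
zero good words are excluded (their count is reported in the result's
attrs) — redistributing their time would require an arbitrary target.
Pipeline cost per word: the sum of **all** triage and retrim interactions
with that word, across annotators and passes, with the final
accepted/rejected status attached.  This deliberately charges the
pipeline for double-checks and rejected candidates (a conservative
accounting that biases against it); a single-pass variant can be had by
pre-filtering the timing log.

Each bootstrap replicate draws a random permutation of the pool and
accumulates cost until the target number of *accepted* words is reached —
rejected words drawn on the way still cost their time.  With a
rejection-free pool this is identical, draw for draw, to sampling N words
directly, which is exactly the baseline procedure.  Sampling is without
replacement within a replicate and with replacement across replicates.
Percent reduction is reported relative to the slower modality's mean;
Cohen's d uses the pooled SD (note that bootstrap distributions are
narrow, so d is large whenever means separate at all).

## Synthetic generator

The generator emulates the structure the analyses assume: trials of eight
disyllabic words at three trained rates laid out sequentially in time
(word durations ~ rate-specific means with 15% CV, plus gaps), omissions
with per-position probabilities rising toward the end of the sequence
(defaults average ~6.4 produced words of 8), seven baseline annotators
segmenting every trial, two pipeline annotators per word, boundary errors
drawn from per-(modality × rate) mixtures (fast speech wider by default),
optional snapping of pipeline deviations to the nearest 20 ms (the
keyboard-shortcut retrim artifact, producing side peaks at ±20 ms), ~5%
rejection, 20% double triage, and log-normal interaction durations sized
so a baseline good word costs ~35 s and a pipeline word ~27 s across
passes.  All randomness flows from one seed through named child streams.

What it does **not** emulate: acoustics of any kind, annotator identity
effects (no per-annotator bias or skill), correlation of errors between
onset and offset of the same token, non-stationarity (fatigue/learning),
or mid-sequence omissions' effect on peak counts.  Passing tests
therefore demonstrate that the statistical machinery behaves correctly
under the assumed error structure — not that real annotators follow it.

Analyses in the test suite and CLI default to scaled problem sizes (a few
hundred tokens, 20–30 particles, a few hundred PSO iterations, bootstrap
targets of 500–5000 words) that keep full runs in seconds while leaving
the estimators well inside their validated tolerance; all sizes are
plain parameters.

## Degenerate inputs and tie-breaks

- Alpha/ICC raise on zero variance rather than returning NaN.
- Largest-remainder allocation breaks remainder ties by stratum order.
- Mixture fits warn (not fail) below 50 deviations.
- A pipeline word with timing events but no final status is an error; a
  zero-duration interaction is allowed with a warning.
- TextGrid parsing rejects UTF-16 input with an explicit transcoding
  message instead of silently converting, and rejects point tiers.
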