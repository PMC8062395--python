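# segrel

Reliability and efficiency statistics for multi-annotator word-boundary
segmentation of speech data.

## The problem

When several phonetically trained annotators mark the onset and offset of
the same spoken words, how consistent are they — and does a streamlined,
task-subdivided annotation pipeline (triage + retrimming of forced-aligned
word candidates) match the reliability of conventional trial-by-trial
TextGrid editing in Praat, at lower cost?

Standard agreement coefficients fail at this question.  Word tokens occur
at widely different times within a trial, so the between-token variance of
boundary times is thousands of times larger than the annotation error.
Chance-corrected coefficients such as Krippendorff's interval alpha
(α = 1 − D_o/D_e) and the one-way intraclass correlation saturate at ≈ 1
and barely move even when the annotation noise is artificially scaled by a
factor of four.

`segrel` implements the distribution-fitting alternative.  For every
boundary, the signed deviation from the cross-annotator median (pooled over
both modalities) is computed, and the deviation distribution is modeled as
a zero-mean mixture of three Gaussians,

    f(x) = θ_n N(x; 0, σ_n²) + θ_m N(x; 0, σ_m²) + θ_w N(x; 0, σ_w²),

with σ_n ∈ [0.0001, 2] ms (boundaries everyone agrees on), σ_m ∈ [1.5, 8] ms
(moderate disagreement), σ_w ∈ [2.5, 40] ms (poor segmentations), and
Σθ = 1.  Parameters are found by a bounded particle-swarm optimizer (60
particles, ≤ 2000 iterations) minimizing the symmetrized Kullback–Leibler
divergence between the binned empirical and model distributions.  The
reliability statistic is the weighted sum **Σ θᵢσᵢ** in milliseconds —
smaller is more reliable — and unlike α or the ICC it scales with the
actual annotation error.

On top of this the package provides:

- `annotation_io` — typed domain records, Praat TextGrid parsing/writing
  (long + short dialects), annotation/timing CSV schemas;
- `deviations` — median references, deviation tables, balanced sampling
  (300 onsets + 300 offsets per modality × rate);
- `classic_metrics` — interval alpha, ICC(1,1), %-within-tolerance, and the
  noise-injection sensitivity sweep exposing their blind spot;
- `mixture_reliability` — the mixture model, KL objective and PSO fit;
- `subset_regression` — the 252 proportion-varied subsets (7 modality
  levels × 36 rate compositions), per-subset fits, and a weighted
  least-squares regression of fitted sigmas on composition with
  θ·(1 − KL) weights and deviation-coded component contrasts;
- `efficiency_bootstrap` — per-word annotator-time aggregation and a
  rejection-aware bootstrap of the hours needed for N well-segmented words;
- `heuristics` — the harmonicity-peak candidate-transcription rule
  (13–14 peaks → 7 disyllabic words, 15–16 → 8);
- `synthetic_data` — a generator of complete synthetic studies (tokens,
  two-modality annotations, timing logs, peak counts) with the error
  structure the analyses assume;
- `cli` — the `segrel` command-line tool wrapping all of the above.

## Worked example

Generate a synthetic study, compute deviations, and fit the mixture:

```sh
$ segrel simulate --seed 7 --out demo
wrote 569 tokens, 10242 annotations, 1878 timing events to demo
$ segrel deviations --annotations demo/annotations.csv --out demo
wrote 1138 references, 10242 deviations to demo
$ segrel fit-mixture demo/deviations.csv --seed 7 --out demo
weighted sigma = 3.835 ms (KL 0.02605, 299 iterations)
$ segrel classic --annotations demo/annotations.csv --out demo
{
  "alpha": 0.9999882279732436,
  "icc": 0.9999882371691333,
  "pct_within_5": 0.8302089435657098,
  ...
}
```

The contrast is the point: alpha and the ICC are pinned at 0.99999 — the
word-layout variance swamps them — while the mixture statistic reports an
interpretable 3.8 ms of annotation error (the generator's error mixtures
imply ≈ 3.6–5.3 ms depending on speaking rate).  The efficiency analysis
on the same study:

```sh
$ segrel efficiency --timing demo/timing.csv --tokens demo/tokens.csv \
    --status demo/word_status.csv --n-good 500 --n-reps 200 --seed 7 --out demo
{
  "baseline_mean_hours": 4.883276635787909,
  "ponss_mean_hours": 3.9923362639927427,
  "mean_diff_hours": 0.8909403717951663,
  "pct_reduction": 18.244724561900934,
  "cohens_d": 17.0357303090827
}
```

i.e. with this generator configuration the pipeline modality needs ~18%
fewer annotator-hours to yield 500 accepted words, after charging it for
all triage/retrim passes including time spent on ultimately rejected
candidates.  `segrel subsets --grid-check` prints the subset-design size
(252), and `segrel sensitivity` runs the noise-injection sweep.

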