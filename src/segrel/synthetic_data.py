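"""Synthetic multi-annotator segmentation studies.

Generates complete studies with the statistical structure the analyses
assume, so every downstream stage can be exercised without real data:

* **Trials** of eight disyllabic words spoken at one of three trained
  rates (fast / medium / slow), laid out sequentially in time with
  rate-dependent word durations and gaps.  Speakers omit words, and the
  omission probability rises with position in the sequence (late words
  are dropped far more often than early ones).
* **Annotations** in two modalities.  Every produced word gets a true
  onset and offset; each annotator's placed boundary is the truth plus a
  draw from a per-(modality x rate) three-Gaussian error mixture.  A
  configurable fraction of the pipeline modality's boundaries is snapped
  to the nearest multiple of 20 ms, emulating the keyboard-shortcut
  retrim step that produces small side peaks at +-20 ms in the deviation
  histogram.
* **Timing logs**.  Pipeline words receive one triage pass (two with
  probability 0.2) and, for a configurable fraction, a retrim pass;
  about 5% of candidates are rejected.  Baseline annotators work whole
  trials.  Interaction durations are log-normal (positive, right-skewed,
  like real human interaction times).
* **Harmonicity peak counts** per trial: two peaks per produced
  disyllabic word, plus occasional +-1 miscounts.

All randomness flows from a single seed through named child streams, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import (
    ANNOTATION_COLUMNS,
    TIMING_COLUMNS,
    Interval,
    IntervalTier,
    Modality,
    Rate,
    TextGridDoc,
    write_textgrid,
)
from .mixture_reliability import MixtureSpec

__all__ = [
    "LogNormalTiming",
    "GeneratorConfig",
    "default_error_models",
    "omission_positions",
    "generate_study",
    "write_study",
]


@dataclass(frozen=True)
class LogNormalTiming:
    """Log-normal interaction-duration model: exp(N(meanlog, sdlog)) seconds."""

    meanlog: float
    sdlog: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.meanlog, self.sdlog, size=n))

    @property
    def mean_seconds(self) -> float:
        return float(np.exp(self.meanlog + 0.5 * self.sdlog**2))


def default_error_models() -> dict[tuple[str, str], MixtureSpec]:
    """Per-(modality, rate) boundary-error mixtures.

    Both modalities share a narrow-dominated mixture; fast speech gets a
    somewhat wider medium/wide structure, since shorter, coarticulated
    words are harder to delimit.
    """
    base = MixtureSpec(sigma=(1.2, 4.0, 15.0), theta=(0.55, 0.35, 0.10))
    fast = MixtureSpec(sigma=(1.4, 5.0, 18.0), theta=(0.45, 0.40, 0.15))
    out: dict[tuple[str, str], MixtureSpec] = {}
    for mod in Modality:
        for rate in Rate:
            out[(mod.value, rate.value)] = fast if rate is Rate.FAST else base
    return out


@dataclass
class GeneratorConfig:
    """Study design and noise structure.

    Defaults emulate the evaluation conditions: 8-word disyllabic trials
    at three rates, 7 baseline annotators correcting every trial, 2
    pipeline annotators per word (random double work), suffix-biased
    omissions averaging ~6.4 produced words per trial, ~5% rejection,
    20% double triage, and 20-ms retrim quantization in the pipeline
    modality only.
    """

    n_speakers: int = 6
    trials_per_speaker: int = 15  # split evenly over the three rates
    words_per_trial: int = 8
    # mean word duration (ms) per rate; gaps between words scale with it
    word_duration_ms: Mapping[str, float] = field(
        default_factory=lambda: {"fast": 300.0, "medium": 450.0, "slow": 600.0}
    )
    duration_cv: float = 0.15  # relative sd of word durations
    gap_fraction: float = 0.6  # inter-word gap as fraction of word duration
    omission_probs: tuple[float, ...] = (
        0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.45, 0.55,
    )
    baseline_annotators: tuple[str, ...] = tuple(f"base{a}" for a in "ABCDEFG")
    ponss_annotators: tuple[str, ...] = tuple(f"pon{a}" for a in "ABCDEFGH")
    ponss_annotators_per_word: int = 2
    error_models: Mapping[tuple[str, str], MixtureSpec] = field(
        default_factory=default_error_models
    )
    quantization_prob: float = 0.1
    quantization_step_ms: float = 20.0
    rejection_prob: float = 0.05
    double_triage_fraction: float = 0.2
    retrim_fraction: float = 1.0  # fraction of pipeline words that get a retrim pass
    triage_timing: LogNormalTiming = LogNormalTiming(meanlog=np.log(6.0), sdlog=0.4)
    retrim_timing: LogNormalTiming = LogNormalTiming(meanlog=np.log(18.0), sdlog=0.4)
    baseline_trial_timing: LogNormalTiming = LogNormalTiming(
        meanlog=np.log(210.0), sdlog=0.3
    )
    peak_miscount_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.omission_probs, dtype=float)
        if len(probs) != self.words_per_trial:
            raise ValueError(
                f"{len(probs)} omission probabilities for "
                f"{self.words_per_trial} words per trial"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("omission probabilities must lie in [0, 1]")
        if np.any(np.diff(probs) < 0):
            raise ValueError("omission probabilities must be non-decreasing in position")
        if not 0 <= self.rejection_prob <= 1:
            raise ValueError("rejection_prob must lie in [0, 1]")
        if not 0 <= self.double_triage_fraction <= 1:
            raise ValueError("double_triage_fraction must lie in [0, 1]")
        if self.quantization_step_ms <= 0:
            raise ValueError("quantization step must be > 0")
        if self.ponss_annotators_per_word > len(self.ponss_annotators):
            raise ValueError("more pipeline annotators per word than roster size")
        for mod in Modality:
            for rate in Rate:
                if (mod.value, rate.value) not in self.error_models:
                    raise ValueError(
                        f"no error model for (modality={mod.value}, rate={rate.value})"
                    )


def _draw_mixture(spec: MixtureSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(spec.theta) / np.sum(spec.theta))
    return rng.normal(0.0, np.asarray(spec.sigma)[comp])


def omission_positions(
    config: GeneratorConfig, rng: np.random.Generator
) -> set[int]:
    """Produced positions (1-based) for one trial draw."""
    probs = np.asarray(config.omission_probs)
    u = rng.uniform(size=len(probs))
    return {i + 1 for i in range(len(probs)) if u[i] >= probs[i]}


_WORD_STOCK = [
    "snavel", "vogel", "tafel", "wortel", "spiegel", "sleutel", "vleugel",
    "stempel", "mantel", "kegel", "gordel", "hamer",
]


def generate_study(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Generate a complete synthetic study.

    Returns a dict of DataFrames: ``tokens``, ``true_boundaries``,
    ``annotations``, ``timing_events``, ``peak_counts``.  Reproducible:
    the same config (including seed) gives identical outputs.
    """
    root = np.random.SeedSequence(config.seed)
    rng_layout, rng_err, rng_flow, rng_time, rng_peak = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    rates = [r.value for r in Rate]
    tokens_rows = []
    truth_rows = []
    trial_meta = []  # (trial_id, rate, produced token rows)
    for s in range(config.n_speakers):
        speaker = f"S{s + 1:02d}"
        for t in range(config.trials_per_speaker):
            rate = rates[t % 3]
            trial_id = f"{speaker}_t{t + 1:03d}"
            produced = sorted(omission_positions(config, rng_layout))
            mean_dur = config.word_duration_ms[rate]
            cursor = rng_layout.uniform(200.0, 600.0)
            trial_tokens = []
            for pos in range(1, config.words_per_trial + 1):
                dur = mean_dur * (
                    1.0 + config.duration_cv * rng_layout.standard_normal()
                )
                dur = max(dur, 0.3 * mean_dur)
                gap = config.gap_fraction * mean_dur * rng_layout.uniform(0.6, 1.4)
                if pos in produced:
                    token_id = f"{trial_id}/w{pos}"
                    label = _WORD_STOCK[(pos - 1) % len(_WORD_STOCK)]
                    tokens_rows.append(
                        (token_id, trial_id, pos, label, speaker, rate)
                    )
                    truth_rows.append((token_id, cursor, cursor + dur))
                    trial_tokens.append((token_id, cursor, cursor + dur))
                cursor += dur + gap
            trial_meta.append((trial_id, rate, trial_tokens))

    tokens = pd.DataFrame(
        tokens_rows,
        columns=["token_id", "trial_id", "position", "label", "speaker_id", "rate"],
    )
    truth = pd.DataFrame(truth_rows, columns=["token_id", "onset_ms", "offset_ms"])

    # --- annotations -------------------------------------------------------
    tok_info = tokens.set_index("token_id")
    truth_info = truth.set_index("token_id")
    ann_rows = []
    retrimmed: dict[str, bool] = {}
    for token_id in tokens["token_id"]:
        rate = tok_info.loc[token_id, "rate"]
        onset = truth_info.loc[token_id, "onset_ms"]
        offset = truth_info.loc[token_id, "offset_ms"]
        retrimmed[token_id] = bool(rng_flow.uniform() < config.retrim_fraction)
        for mod in Modality:
            if mod is Modality.BASELINE:
                annotators = config.baseline_annotators
            else:
                annotators = tuple(
                    rng_flow.choice(
                        config.ponss_annotators,
                        size=config.ponss_annotators_per_word,
                        replace=False,
                    )
                )
            spec = config.error_models[(mod.value, rate)]
            errs = _draw_mixture(spec, rng_err, 2 * len(annotators))
            quantize = (
                mod is Modality.PONSS
                and retrimmed[token_id]
                and config.quantization_prob > 0
            )
            if quantize:
                snap = rng_err.uniform(size=errs.shape) < config.quantization_prob
                step = config.quantization_step_ms
                errs = np.where(snap, np.round(errs / step) * step, errs)
            k = 0
            for ann in annotators:
                for bnd, true_t in (("onset", onset), ("offset", offset)):
                    ann_rows.append(
                        (
                            token_id,
                            tok_info.loc[token_id, "trial_id"],
                            int(tok_info.loc[token_id, "position"]),
                            tok_info.loc[token_id, "label"],
                            tok_info.loc[token_id, "speaker_id"],
                            rate,
                            mod.value,
                            ann,
                            bnd,
                            max(0.0, true_t + errs[k]),
                        )
                    )
                    k += 1
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)

    # --- timing events ------------------------------------------------------
    timing_rows = []
    clock = 0.0
    for token_id in tokens["token_id"]:
        rejected = bool(rng_flow.uniform() < config.rejection_prob)
        n_triage = 2 if rng_flow.uniform() < config.double_triage_fraction else 1
        passes = []
        for p in range(n_triage):
            ann = str(rng_flow.choice(config.ponss_annotators))
            dur = float(config.triage_timing.draw(rng_time, 1)[0])
            last = p == n_triage - 1 and not retrimmed[token_id]
            if rejected and last:
                outcome = "rejected"
            elif retrimmed[token_id] and p == n_triage - 1:
                outcome = "retrim_requested"
            else:
                outcome = "accepted"
            passes.append(("triage", ann, dur, outcome))
        if retrimmed[token_id]:
            ann = str(rng_flow.choice(config.ponss_annotators))
            dur = float(config.retrim_timing.draw(rng_time, 1)[0])
            passes.append(("retrim", ann, dur, "rejected" if rejected else "saved"))
        for task, ann, dur, outcome in passes:
            timing_rows.append(
                (token_id, ann, Modality.PONSS.value, task, clock, clock + dur, outcome)
            )
            clock += dur + 1.0
    for trial_id, rate, trial_tokens in trial_meta:
        for ann in config.baseline_annotators:
            dur = float(config.baseline_trial_timing.draw(rng_time, 1)[0])
            timing_rows.append(
                (
                    trial_id,
                    ann,
                    Modality.BASELINE.value,
                    "baseline_trial",
                    clock,
                    clock + dur,
                    "saved",
                )
            )
            clock += dur + 1.0
    timing = pd.DataFrame(timing_rows, columns=TIMING_COLUMNS)

    # --- harmonicity peak counts -------------------------------------------
    produced_per_trial = tokens.groupby("trial_id").size()
    peak_rows = []
    for trial_id, _, _ in trial_meta:
        n_words = int(produced_per_trial.get(trial_id, 0))
        noise = 0
        if rng_peak.uniform() < config.peak_miscount_prob:
            noise = int(rng_peak.choice([-1, 1]))
        peak_rows.append((trial_id, max(0, 2 * n_words + noise)))
    peaks = pd.DataFrame(peak_rows, columns=["trial_id", "n_peaks"])

    status = pd.DataFrame(
        {
            "word_id": list(retrimmed),
            "retrimmed": list(retrimmed.values()),
        }
    )
    rejected_map = (
        timing[timing["outcome"] == "rejected"]["unit_id"].unique()
    )
    status["accepted"] = ~status["word_id"].isin(rejected_map)

    return {
        "tokens": tokens,
        "true_boundaries": truth,
        "annotations": annotations,
        "timing_events": timing,
        "peak_counts": peaks,
        "word_status": status,
    }


def write_study(
    study: dict[str, pd.DataFrame],
    out_dir: str | Path,
    textgrids: bool = False,
) -> None:
    """Write a generated study as CSV files (and optionally baseline
    TextGrids, one per trial x annotator, from the annotation table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study["tokens"].to_csv(out / "tokens.csv", index=False)
    study["true_boundaries"].to_csv(out / "true_boundaries.csv", index=False)
    study["annotations"].to_csv(out / "annotations.csv", index=False)
    study["timing_events"].to_csv(out / "timing.csv", index=False)
    study["peak_counts"].to_csv(out / "peaks.csv", index=False)
    study["word_status"].to_csv(out / "word_status.csv", index=False)
    if textgrids:
        tg_dir = out / "textgrids"
        tg_dir.mkdir(exist_ok=True)
        ann = study["annotations"]
        base = ann[ann["modality"] == Modality.BASELINE.value]
        for (trial_id, annotator), grp in base.groupby(["trial_id", "annotator_id"]):
            doc = _annotations_to_textgrid(grp)
            (tg_dir / f"{trial_id}__{annotator}.TextGrid").write_text(
                write_textgrid(doc)
            )


def _annotations_to_textgrid(group: pd.DataFrame) -> TextGridDoc:
    """One annotator's segmentation of one trial as a word-tier TextGrid."""
    wide = group.pivot_table(
        index=["token_id", "position", "label"],
        columns="boundary",
        values="time_ms",
        aggfunc="first",
    ).reset_index()
    wide = wide.sort_values("position")
    intervals = []
    cursor = 0.0
    for _, row in wide.iterrows():
        onset_s = row["onset"] / 1000.0
        offset_s = max(row["offset"], row["onset"]) / 1000.0
        if onset_s > cursor:
            intervals.append(Interval(cursor, onset_s, ""))
        elif onset_s < cursor:
            onset_s = cursor
        intervals.append(Interval(onset_s, offset_s, str(row["label"])))
        cursor = offset_s
    xmax = cursor + 0.5
    intervals.append(Interval(cursor, xmax, ""))
    tier = IntervalTier("words", 0.0, xmax, intervals)
    return TextGridDoc(0.0, xmax, [tier])
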