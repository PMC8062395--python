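"""Annotator-time efficiency: per-word costs and rejection-aware bootstrap.

The question: how many annotator-hours does each modality need to yield
N well-segmented words?  Baseline (Praat) annotators work trial by
trial, so a trial's wall-clock time is divided equally over the good
words it produced.  In the streamlined pipeline, a word candidate may be
triaged and retrimmed several times by several annotators, and some
candidates are ultimately rejected; every interaction with a word is
summed into that word's cost, and its final accepted/rejected status is
kept.

The bootstrap then draws replicate samples of words and accumulates
their costs.  For the pipeline modality, rejected words cost time but do
not count toward the target, so each replicate keeps drawing until it
holds N accepted words — the honest, rejection-inflated price of N good
words.  Baseline pools contain accepted words only (rejections are
implicit in the per-trial division), so a replicate is simply N drawn
words.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Modality, Task

__all__ = [
    "WORD_TIME_COLUMNS",
    "BootstrapDistribution",
    "baseline_word_times",
    "ponss_word_times",
    "bootstrap_hours",
    "compare_modalities",
]

WORD_TIME_COLUMNS = ["word_id", "modality", "total_seconds", "accepted"]


@dataclass
class BootstrapDistribution:
    """Replicate totals (hours) for one modality at a fixed target N."""

    modality: str
    n_good: int
    replicate_hours: np.ndarray

    def __post_init__(self) -> None:
        self.replicate_hours = np.asarray(self.replicate_hours, dtype=float)
        if np.any(self.replicate_hours <= 0):
            raise ValueError("replicate totals must be positive")

    @property
    def mean(self) -> float:
        return float(self.replicate_hours.mean())

    @property
    def sd(self) -> float:
        return float(self.replicate_hours.std(ddof=1))


def _durations(timing: pd.DataFrame) -> pd.Series:
    d = timing["t_end_s"] - timing["t_start_s"]
    if (d < 0).any():
        row = int(timing.index[d < 0][0])
        raise ValueError(f"row {row}: negative event duration")
    return d


def baseline_word_times(
    timing: pd.DataFrame, good_words_per_trial: Mapping[str, int]
) -> pd.DataFrame:
    """Per-word cost of baseline annotation.

    Each ``baseline_trial`` event's duration is split equally over the
    trial's good words (per that annotator's own event — no cross-
    annotator pooling).  Trials with zero good words contribute no
    records; their count is reported in ``df.attrs['zero_good_trials']``.
    """
    events = timing[timing["task"] == Task.BASELINE_TRIAL.value]
    durations = _durations(events)
    rows = []
    zero_good = 0
    for (_, ev), dur in zip(events.iterrows(), durations):
        n_good = int(good_words_per_trial.get(ev["unit_id"], 0))
        if n_good < 0:
            raise ValueError(f"trial {ev['unit_id']}: negative good-word count")
        if n_good == 0:
            zero_good += 1
            continue
        per_word = dur / n_good
        for k in range(n_good):
            rows.append(
                (
                    f"{ev['unit_id']}::{ev['annotator_id']}::w{k + 1}",
                    Modality.BASELINE.value,
                    per_word,
                    True,
                )
            )
    df = pd.DataFrame(rows, columns=WORD_TIME_COLUMNS)
    df.attrs["zero_good_trials"] = zero_good
    return df


def ponss_word_times(
    timing: pd.DataFrame, final_status: Mapping[str, bool]
) -> pd.DataFrame:
    """Per-word cost of pipeline annotation.

    Sums the durations of **all** triage and retrim interactions with
    each word across annotators and passes; ``final_status`` maps word id
    to acceptance into the finished dataset.
    """
    import warnings

    events = timing[timing["task"].isin([Task.TRIAGE.value, Task.RETRIM.value])]
    dur = _durations(events)
    totals = dur.groupby(events["unit_id"]).sum()
    missing = [w for w in totals.index if w not in final_status]
    if missing:
        raise ValueError(
            f"{len(missing)} words have timing events but no final status, "
            f"e.g. {missing[0]!r}"
        )
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} words have zero total interaction time",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "word_id": totals.index,
            "modality": Modality.PONSS.value,
            "total_seconds": totals.values,
            "accepted": [bool(final_status[w]) for w in totals.index],
        }
    )


def bootstrap_hours(
    records: pd.DataFrame,
    n_good: int = 5000,
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapDistribution:
    """Bootstrap the total cost (hours) of *n_good* accepted words.

    Each replicate draws words without replacement, in a random order,
    and accumulates total time until *n_good* accepted words have been
    drawn; rejected words drawn along the way still cost their time.
    With a rejection-free pool this reduces exactly to drawing *n_good*
    words.  Replicates are independent draws from the same pool
    (with replacement across replicates), reproducible under *seed*.
    """
    times = records["total_seconds"].to_numpy(dtype=float)
    accepted = records["accepted"].to_numpy(dtype=bool)
    n_accepted = int(accepted.sum())
    if n_accepted < n_good:
        raise ValueError(
            f"pool holds {n_accepted} accepted words; {n_good} required"
        )
    modality = records["modality"].iloc[0] if len(records) else "unknown"
    rng = np.random.default_rng(seed)
    n_pool = len(records)
    totals = np.empty(n_reps)
    for r in range(n_reps):
        order = rng.permutation(n_pool)
        acc_count = np.cumsum(accepted[order])
        stop = int(np.searchsorted(acc_count, n_good)) + 1
        totals[r] = times[order[:stop]].sum()
    return BootstrapDistribution(
        modality=str(modality), n_good=n_good, replicate_hours=totals / 3600.0
    )


def compare_modalities(
    a: BootstrapDistribution, b: BootstrapDistribution
) -> dict[str, float]:
    """Mean difference (h), percent reduction, and Cohen's d between two
    bootstrap distributions with the same target N.

    Percent reduction is the mean difference relative to the *slower*
    modality's mean.  Cohen's d uses the pooled standard deviation; a
    zero pooled SD with a nonzero difference yields infinite d with a
    warning.
    """
    import warnings

    if a.n_good != b.n_good:
        raise ValueError("distributions target different n_good")
    diff = abs(a.mean - b.mean)
    slower = max(a.mean, b.mean)
    pooled_sd = float(np.sqrt((a.sd**2 + b.sd**2) / 2.0))
    if pooled_sd == 0:
        if diff == 0:
            d = 0.0
        else:
            warnings.warn("zero pooled SD with nonzero difference", stacklevel=2)
            d = float("inf")
    else:
        d = diff / pooled_sd
    return {
        "mean_diff_hours": diff,
        "pct_reduction": 100.0 * diff / slower if slower > 0 else 0.0,
        "cohens_d": d,
    }
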