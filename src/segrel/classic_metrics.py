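"""Conventional inter-rater reliability coefficients and their sensitivity.

Krippendorff's alpha (interval metric), the one-way random-effects
intraclass correlation ICC(1,1), and percentage-within-tolerance are the
measures speech researchers conventionally reach for.  On boundary-time
data they share a blind spot: word tokens occur at wildly different times
within a trial, so between-unit variance dwarfs the within-unit
annotation error by orders of magnitude, and chance-corrected
coefficients saturate at ~1 regardless of how (im)precise annotators
actually are.  :func:`sensitivity_sweep` demonstrates this by shrinking
or inflating the deviations around each unit median (factor ``lam``)
and/or adding Gaussian jitter, then recomputing every coefficient —
alongside the mixture-based weighted sigma, which does respond.

A *reliability matrix* here is a pandas DataFrame of unit rows x rater
columns holding real values, with NaN for missing cells.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "reliability_matrix",
    "krippendorff_alpha_interval",
    "icc_oneway",
    "pct_within_tolerance",
    "sensitivity_sweep",
]


def reliability_matrix(annotations: pd.DataFrame) -> pd.DataFrame:
    """Pivot an annotation table into units x raters.

    Units are (token_id, boundary) pairs; raters are annotator x modality
    combinations (the same person may rate in both modalities, which are
    distinct rating occasions).
    """
    df = annotations.copy()
    df["rater"] = df["annotator_id"].astype(str) + "|" + df["modality"].astype(str)
    return df.pivot_table(
        index=["token_id", "boundary"], columns="rater", values="time_ms",
        aggfunc="first",
    )


def _validate_matrix(m: pd.DataFrame) -> np.ndarray:
    values = np.asarray(m, dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("reliability matrix needs >= 2 units and >= 2 raters")
    counts = np.sum(~np.isnan(values), axis=1)
    if not np.any(counts >= 2):
        raise ValueError("no unit has >= 2 ratings; nothing is pairable")
    return values


def krippendorff_alpha_interval(m: pd.DataFrame) -> float:
    """Krippendorff's alpha with the interval difference function.

    alpha = 1 - D_o / D_e with delta(v, v') = (v - v')^2.  Observed
    disagreement averages within-unit pairs (each unit's pair sum divided
    by m_u - 1); expected disagreement pairs all pairable values across
    units.  Units with fewer than two ratings are excluded entirely.
    Raises if expected disagreement is zero (all pairable values equal).
    """
    values = _validate_matrix(m)
    counts = np.sum(~np.isnan(values), axis=1)
    keep = counts >= 2
    values = values[keep]
    counts = counts[keep]

    # Sum_{i != j in unit} (v_i - v_j)^2 = 2 m Sum v^2 - 2 (Sum v)^2
    s1 = np.nansum(values, axis=1)
    s2 = np.nansum(values**2, axis=1)
    within = 2.0 * counts * s2 - 2.0 * s1**2
    n = counts.sum()
    d_obs = float(np.sum(within / (counts - 1))) / n

    pooled = values[~np.isnan(values)]
    total1 = pooled.sum()
    total2 = (pooled**2).sum()
    cross = 2.0 * n * total2 - 2.0 * total1**2
    if cross <= 0:
        raise ValueError(
            "expected disagreement is zero (all pairable values identical); "
            "alpha is undefined"
        )
    d_exp = cross / (n * (n - 1))
    return 1.0 - d_obs / d_exp


def icc_oneway(m: pd.DataFrame) -> float:
    """One-way random-effects intraclass correlation, ICC(1,1).

    From the one-way ANOVA decomposition over units:
    ``(MSB - MSW) / (MSB + (k0 - 1) MSW)`` where for unbalanced designs
    ``k0 = (N - sum(k_u^2)/N) / (n_units - 1)`` is the standard effective
    group size.  Raises when total variance is zero.
    """
    values = _validate_matrix(m)
    counts = np.sum(~np.isnan(values), axis=1)
    keep = counts >= 1
    values, counts = values[keep], counts[keep]
    n_units = values.shape[0]
    total_n = int(counts.sum())
    if n_units < 2 or total_n <= n_units:
        raise ValueError("ICC needs >= 2 units and at least one unit with >= 2 ratings")

    grand = np.nansum(values) / total_n
    unit_means = np.nanmean(values, axis=1)
    ssb = float(np.sum(counts * (unit_means - grand) ** 2))
    ssw = float(np.nansum((values - unit_means[:, None]) ** 2))
    if ssb + ssw == 0:
        raise ValueError("zero total variance; ICC is undefined")
    msb = ssb / (n_units - 1)
    msw = ssw / (total_n - n_units)
    k0 = (total_n - float(np.sum(counts**2)) / total_n) / (n_units - 1)
    return (msb - msw) / (msb + (k0 - 1.0) * msw)


def pct_within_tolerance(deviations: Sequence[float], tol_ms: float) -> float:
    """Fraction of deviations with ``|d| <= tol_ms`` (inclusive)."""
    if tol_ms <= 0:
        raise ValueError("tol_ms must be > 0")
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("empty deviation sequence")
    return float(np.mean(np.abs(d) <= tol_ms))


def sensitivity_sweep(
    annotations: pd.DataFrame,
    references: pd.DataFrame,
    lambdas: Sequence[float],
    noise_sds: Sequence[float],
    tolerances: Sequence[float],
    seed: int,
    pso_config=None,
    binning=None,
) -> pd.DataFrame:
    """Recompute every reliability measure on noise-tweaked datasets.

    For each (lam, sd) grid point, boundary times are rebuilt as
    ``median + lam * deviation + eps`` with ``eps ~ N(0, sd^2)``: lam < 1
    artificially *removes* annotation noise, lam > 1 adds it.  Alpha, the
    ICC, the within-tolerance percentages, and the mixture-model weighted
    sigma are then recomputed on the tweaked data.  Reproducible under
    *seed* (one child seed per grid point).
    """
    from .mixture_reliability import KlBinning, PsoConfig, pso_fit, weighted_sigma_summary

    if len(lambdas) == 0 or len(noise_sds) == 0:
        raise ValueError("lambda and noise grids must be non-empty")
    if pso_config is None:
        pso_config = PsoConfig(n_particles=20, max_iter=300)
    if binning is None:
        binning = KlBinning()

    base = annotations.merge(
        references[["token_id", "boundary", "median_ms"]],
        on=["token_id", "boundary"],
    )
    base["deviation_ms"] = base["time_ms"] - base["median_ms"]

    rows = []
    for i, (lam, sd) in enumerate(product(lambdas, noise_sds)):
        child = np.random.default_rng([seed, i])
        eps = child.normal(0.0, sd, size=len(base)) if sd > 0 else 0.0
        tweaked = base.copy()
        tweaked["deviation_ms"] = lam * base["deviation_ms"] + eps
        tweaked["time_ms"] = tweaked["median_ms"] + tweaked["deviation_ms"]

        matrix = reliability_matrix(tweaked)
        row = {"lam": lam, "noise_sd": sd, "seed": seed}
        try:
            row["alpha"] = krippendorff_alpha_interval(matrix)
            row["icc"] = icc_oneway(matrix)
        except ValueError as exc:
            raise ValueError(f"grid point (lam={lam}, sd={sd}): {exc}") from exc
        for tol in tolerances:
            row[f"pct_within_{tol:g}"] = pct_within_tolerance(
                tweaked["deviation_ms"], tol
            )
        fit_cfg = PsoConfig(
            n_particles=pso_config.n_particles,
            max_iter=pso_config.max_iter,
            inertia=pso_config.inertia,
            cognitive=pso_config.cognitive,
            social=pso_config.social,
            velocity_clamp_fraction=pso_config.velocity_clamp_fraction,
            early_stop_tol=pso_config.early_stop_tol,
            early_stop_patience=pso_config.early_stop_patience,
            seed=int(child.integers(2**31)),
        )
        fit = pso_fit(tweaked["deviation_ms"].to_numpy(), fit_cfg, binning=binning)
        row["weighted_sigma"] = weighted_sigma_summary(fit)
        rows.append(row)
    return pd.DataFrame(rows)
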