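"""Proportion-varied subsets and the weighted sigma regression.

To estimate how modality and speaking rate affect segmentation
reliability, the balanced deviation sample is resampled into subsets
whose composition is varied on a grid: the manual (baseline) proportion
runs 20%..80% in steps of 10%, and the three speaking-rate proportions
each run 10%..80% in steps of 10% under the constraint that they sum to
100%.  Exhaustive crossing yields 36 rate compositions x 7 modality
levels = 252 subsets.  The mixture model is fitted to each subset, every
particle of each final swarm contributes one row per component, and a
weighted least-squares regression predicts the fitted component sigmas
from the subset proportions.

Regression weights are ``theta_component x max(0, 1 - KL)``: a
particle's sigma for a component counts in proportion to how much of the
mixture that component explains and how good the overall fit is.
Predictors are the POnSS, fast, and slow proportions (the manual and
medium proportions are linearly determined by these and are excluded),
a sum-to-zero (deviation) coded component factor, and their
interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mixture_reliability import COMPONENTS, KlBinning, PsoConfig, pso_fit

__all__ = [
    "ProportionCell",
    "ROW_COLUMNS",
    "build_proportion_grid",
    "draw_subset",
    "fit_all_subsets",
    "sigma_regression",
]

ROW_COLUMNS = [
    "subset_id",
    "particle",
    "component",
    "sigma",
    "weight",
    "p_ponss",
    "p_fast",
    "p_slow",
]


@dataclass(frozen=True)
class ProportionCell:
    """Target composition of one subset (proportions of the total size)."""

    p_manual: float
    p_fast: float
    p_medium: float
    p_slow: float

    def __post_init__(self) -> None:
        rates = (self.p_fast, self.p_medium, self.p_slow)
        if abs(sum(rates) - 1.0) > 1e-9:
            raise ValueError(f"rate proportions must sum to 1, got {rates}")
        if not all(0.1 - 1e-9 <= p <= 0.8 + 1e-9 for p in rates):
            raise ValueError(f"rate proportions must lie in [0.1, 0.8], got {rates}")
        if not 0.2 - 1e-9 <= self.p_manual <= 0.8 + 1e-9:
            raise ValueError(f"p_manual must lie in [0.2, 0.8], got {self.p_manual}")

    @property
    def p_ponss(self) -> float:
        return 1.0 - self.p_manual


def build_proportion_grid() -> list[ProportionCell]:
    """All 252 proportion cells, in deterministic order.

    Rate compositions are the 36 ways to split 10 tenths over three rates
    with each rate getting 1..8 tenths; each is crossed with the 7 manual
    proportions 0.2, 0.3, ..., 0.8.
    """
    cells = []
    for manual_tenths in range(2, 9):
        for fast in range(1, 9):
            for medium in range(1, 9):
                slow = 10 - fast - medium
                if not 1 <= slow <= 8:
                    continue
                cells.append(
                    ProportionCell(
                        p_manual=manual_tenths / 10.0,
                        p_fast=fast / 10.0,
                        p_medium=medium / 10.0,
                        p_slow=slow / 10.0,
                    )
                )
    return cells


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of *total* by target fractions: floors first,
    then +1 to the largest remainders (index order breaks ties)."""
    exact = total * fractions
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def draw_subset(
    sample: pd.DataFrame,
    cell: ProportionCell,
    size: int,
    seed: int,
) -> pd.DataFrame:
    """Draw a subset of *size* deviation records matching *cell*.

    Modality and rate compositions are crossed independently (stratum
    fraction = p_modality x p_rate) and converted to integer counts by
    largest-remainder allocation, so marginal counts match the cell
    within rounding.  Sampling is without replacement within each
    stratum, reproducible under *seed*.
    """
    strata = [
        (mod, rate)
        for mod in ("ponss", "baseline")
        for rate in ("fast", "medium", "slow")
    ]
    p_mod = {"ponss": cell.p_ponss, "baseline": cell.p_manual}
    p_rate = {"fast": cell.p_fast, "medium": cell.p_medium, "slow": cell.p_slow}
    fractions = np.array([p_mod[m] * p_rate[r] for m, r in strata])
    counts = _largest_remainder(size, fractions)

    rng = np.random.default_rng(seed)
    parts = []
    for (mod, rate), k in zip(strata, counts):
        if k == 0:
            continue
        pool = sample[(sample["modality"] == mod) & (sample["rate"] == rate)]
        if len(pool) < k:
            raise ValueError(
                f"stratum (modality={mod}, rate={rate}) has {len(pool)} records; "
                f"{k} needed for cell {cell}"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        parts.append(pool.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def _subset_seeds(master_seed: int, index: int) -> tuple[int, int]:
    """Per-subset (draw, fit) seeds derived from a master seed by counter."""
    state = np.random.SeedSequence([master_seed, index]).generate_state(2)
    return int(state[0] & 0x7FFFFFFF), int(state[1] & 0x7FFFFFFF)


def fit_all_subsets(
    sample: pd.DataFrame,
    grid: list[ProportionCell],
    size: int,
    pso_config: PsoConfig = PsoConfig(),
    master_seed: int = 0,
    binning: KlBinning = KlBinning(),
    best_only: bool = False,
) -> pd.DataFrame:
    """Fit the mixture to every subset of the grid; return regression rows.

    One row per (subset x final-iteration particle x component), or per
    (subset x component) with ``best_only``.  Each row carries the
    particle's fitted sigma for the component, the regression weight
    ``theta x max(0, 1 - KL)``, and the subset's predictor proportions.
    Per-subset seeds derive deterministically from *master_seed*; a
    failed subset fit is recorded (``NaN`` sigma rows are skipped and the
    failure noted in ``df.attrs['failures']``) and the run continues.
    """
    rows = []
    failures = []
    for i, cell in enumerate(grid):
        draw_seed, fit_seed = _subset_seeds(master_seed, i)
        try:
            subset = draw_subset(sample, cell, size, draw_seed)
            cfg = PsoConfig(
                n_particles=pso_config.n_particles,
                max_iter=pso_config.max_iter,
                inertia=pso_config.inertia,
                cognitive=pso_config.cognitive,
                social=pso_config.social,
                velocity_clamp_fraction=pso_config.velocity_clamp_fraction,
                early_stop_tol=pso_config.early_stop_tol,
                early_stop_patience=pso_config.early_stop_patience,
                seed=fit_seed,
            )
            fit = pso_fit(subset["deviation_ms"].to_numpy(), cfg, binning=binning)
        except ValueError as exc:
            failures.append((i, str(exc)))
            continue
        chosen = (
            [(fit.best_spec, fit.best_kl)] if best_only else fit.particles
        )
        for p_idx, (spec, kl) in enumerate(chosen):
            w_fit = max(0.0, 1.0 - kl)
            for c_idx, comp in enumerate(COMPONENTS):
                rows.append(
                    (
                        i,
                        p_idx,
                        comp,
                        spec.sigma[c_idx],
                        spec.theta[c_idx] * w_fit,
                        cell.p_ponss,
                        cell.p_fast,
                        cell.p_slow,
                    )
                )
    df = pd.DataFrame(rows, columns=ROW_COLUMNS)
    df.attrs["failures"] = failures
    return df


def _design_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    """Predictors with sum-to-zero component contrasts and interactions."""
    comp = rows["component"]
    # Deviation coding over (narrow, medium, wide): wide is the implicit
    # reference level (-1, -1).
    c1 = comp.map({"narrow": 1.0, "medium": 0.0, "wide": -1.0})
    c2 = comp.map({"narrow": 0.0, "medium": 1.0, "wide": -1.0})
    if c1.isna().any():
        bad = sorted(set(comp[c1.isna()]))
        raise ValueError(f"unknown component levels: {bad}")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "p_ponss": rows["p_ponss"].astype(float),
            "p_fast": rows["p_fast"].astype(float),
            "p_slow": rows["p_slow"].astype(float),
            "comp_narrow": c1,
            "comp_medium": c2,
        }
    )
    for pred in ("p_ponss", "p_fast", "p_slow"):
        X[f"{pred}:comp_narrow"] = X[pred] * X["comp_narrow"]
        X[f"{pred}:comp_medium"] = X[pred] * X["comp_medium"]
    return X


def sigma_regression(rows: pd.DataFrame) -> pd.DataFrame:
    """Weighted least squares of fitted sigmas on subset proportions.

    Returns a table of (term, estimate, se).  Weights below or at zero
    are dropped (a particle whose KL exceeded 1 carries no information).
    Raises on a rank-deficient design, naming the collinear columns.
    """
    for pred in ("p_ponss", "p_fast", "p_slow"):
        if rows[pred].nunique() < 2:
            raise ValueError(f"predictor {pred} has fewer than 2 distinct values")
    keep = rows["weight"] > 0
    if not keep.any():
        raise ValueError("all regression weights are zero")
    rows = rows.loc[keep]
    X = _design_matrix(rows)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
        pairs = [
            (X.columns[1 + a], X.columns[1 + b])
            for a in range(corr.shape[0])
            for b in range(a + 1, corr.shape[0])
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {pairs}")
    model = sm.WLS(rows["sigma"].astype(float), X, weights=rows["weight"].astype(float))
    res = model.fit()
    return pd.DataFrame(
        {"term": X.columns, "estimate": res.params.values, "se": res.bse.values}
    )
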