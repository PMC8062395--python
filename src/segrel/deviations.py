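"""Median references and boundary-time deviations.

The reliability analyses are built on one quantity: for every annotated
boundary, the signed difference (ms) between the annotator's placed time
and the median time for that token/boundary, pooled across **all**
annotators and **both** modalities.  Pooling both modalities gives every
record the same reference, so modality differences show up as differences
in deviation spread rather than in the reference itself.

Schemas (pandas DataFrames):

* annotations — :data:`segrel.annotation_io.ANNOTATION_COLUMNS`
* references  — token_id, boundary, median_ms, n_contributing
* deviations  — token_id, boundary, modality, rate, annotator_id, deviation_ms
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .annotation_io import Boundary, Modality, Rate

__all__ = [
    "REFERENCE_COLUMNS",
    "DEVIATION_COLUMNS",
    "reference_medians",
    "compute_deviations",
    "balanced_sample",
]

REFERENCE_COLUMNS = ["token_id", "boundary", "median_ms", "n_contributing"]
DEVIATION_COLUMNS = [
    "token_id",
    "boundary",
    "modality",
    "rate",
    "annotator_id",
    "deviation_ms",
]


def reference_medians(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per (token, boundary) median time across all annotators and modalities.

    Even-sized groups use the mean-of-central-values convention.  Singleton
    groups are allowed; their sole annotation will deviate by 0.
    """
    if annotations.empty:
        raise ValueError("no annotations supplied")
    grouped = annotations.groupby(["token_id", "boundary"], sort=True)["time_ms"]
    out = grouped.agg(median_ms="median", n_contributing="size").reset_index()
    return out[REFERENCE_COLUMNS]


def compute_deviations(
    annotations: pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    """One deviation record per annotation: ``time_ms - median_ms``."""
    merged = annotations.merge(
        references[["token_id", "boundary", "median_ms"]],
        on=["token_id", "boundary"],
        how="left",
        validate="many_to_one",
    )
    missing = merged["median_ms"].isna()
    if missing.any():
        tok = merged.loc[missing, ["token_id", "boundary"]].iloc[0]
        raise ValueError(
            f"no reference median for token {tok.token_id!r} "
            f"boundary {tok.boundary!r}"
        )
    merged["deviation_ms"] = merged["time_ms"] - merged["median_ms"]
    return merged[DEVIATION_COLUMNS]


def balanced_sample(
    deviations: pd.DataFrame,
    per_cell_n: int,
    seed: int,
    modalities: tuple[str, ...] = tuple(m.value for m in Modality),
    rates: tuple[str, ...] = tuple(r.value for r in Rate),
    boundaries: tuple[str, ...] = tuple(b.value for b in Boundary),
) -> pd.DataFrame:
    """Draw exactly *per_cell_n* records per (modality, rate, boundary) cell.

    Sampling is without replacement and reproducible under *seed*.  The
    default design is the evaluation layout: 300 onsets and 300 offsets
    per modality per speaking rate -> 3600 records.
    """
    if per_cell_n < 1:
        raise ValueError("per_cell_n must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for mod, rate, bnd in product(modalities, rates, boundaries):
        cell = deviations[
            (deviations["modality"] == mod)
            & (deviations["rate"] == rate)
            & (deviations["boundary"] == bnd)
        ]
        if len(cell) < per_cell_n:
            raise ValueError(
                f"cell (modality={mod}, rate={rate}, boundary={bnd}) has only "
                f"{len(cell)} records; {per_cell_n} requested"
            )
        idx = rng.choice(len(cell), size=per_cell_n, replace=False)
        parts.append(cell.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)
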