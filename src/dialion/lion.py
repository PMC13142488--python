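"""Local Inference of ION-level missingness using Neighborhood estimation.

Cross-run ion intensity vectors are assembled per precursor and level (MS1
and MS2 are processed separately, with no cross-level borrowing). An entry
is treated as missing when its XIC quality is low or its quantity is zero or
absent; ions missing in too many runs are excluded outright. Each remaining
missing entry is filled with ``scale`` times the minimum observed quantity
of the same ion among runs of the same biological condition — the
"neighborhood". The neighborhood never crosses conditions; an ion with a
fully missing condition cannot be filled there and is excluded.

The ion table is a long-format DataFrame with one row per ion x run and
columns ``precursor_id, protein_group, ion_id, level, run_id, quantity,
quality, missing, inferred`` — the tabular realization of a cross-run ion
vector per (precursor_id, ion_id, level) group.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import SampleMetadata

__all__ = [
    "flag_missing",
    "exclude_sparse_ions",
    "lion_infer",
    "ION_KEY",
    "DEFAULT_MIN_QUALITY",
    "DEFAULT_MAX_MISSING_FRACTION",
    "DEFAULT_SCALE",
]

ION_KEY = ["precursor_id", "ion_id", "level"]

DEFAULT_MIN_QUALITY = 0.3
DEFAULT_MAX_MISSING_FRACTION = 0.5
DEFAULT_SCALE = 1.0


def flag_missing(ion_table: pd.DataFrame, min_quality: float = DEFAULT_MIN_QUALITY) -> pd.DataFrame:
    """Mark entries with low XIC quality or zero/absent quantity as missing."""
    if not 0.0 <= min_quality <= 1.0:
        raise ValueError("min_quality must be in [0, 1]")
    df = ion_table.copy()
    q = df["quantity"].to_numpy(dtype=float, na_value=np.nan)
    qual = df["quality"].to_numpy(dtype=float, na_value=np.nan)
    df["missing"] = np.isnan(q) | (q == 0) | (qual < min_quality)
    return df


def exclude_sparse_ions(
    ion_table: pd.DataFrame,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> pd.DataFrame:
    """Drop ions whose cross-run missing fraction exceeds the threshold."""
    if not 0.0 < max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = ion_table.groupby(ION_KEY, sort=False)["missing"].transform("mean")
    return ion_table.loc[frac <= max_missing_fraction].reset_index(drop=True)


def lion_infer(
    ion_table: pd.DataFrame,
    metadata: SampleMetadata,
    scale: float = DEFAULT_SCALE,
    drop_unfillable: bool = True,
) -> pd.DataFrame:
    """Fill missing entries from same-condition minima.

    Each missing entry becomes ``scale`` x the minimum non-missing quantity
    of its ion among runs sharing the entry's condition. Observed entries are
    untouched; ``inferred`` marks exactly the filled entries. Ions with a
    condition that has no observed value cannot be completed; they are
    dropped when ``drop_unfillable`` (the pipeline default) or left missing
    otherwise.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    df = ion_table.copy()
    cond = df["run_id"].map(metadata.condition_of)
    if cond.isna().any():
        bad = sorted(df.loc[cond.isna(), "run_id"].unique())
        raise ValueError(f"runs absent from sample metadata: {bad}")
    df["_condition"] = cond
    observed = df["quantity"].where(~df["missing"], np.nan)
    local_min = observed.groupby(
        [df[k] for k in ION_KEY] + [df["_condition"]], sort=False
    ).transform("min")
    fill = scale * local_min
    fillable = df["missing"] & fill.notna()
    df["inferred"] = fillable
    df.loc[fillable, "quantity"] = fill[fillable]
    df.loc[fillable, "missing"] = False
    df = df.drop(columns="_condition")
    if drop_unfillable:
        still = df.groupby(ION_KEY, sort=False)["missing"].transform("any")
        df = df.loc[~still].reset_index(drop=True)
    return df


def ion_vector(
    ion_table: pd.DataFrame,
    precursor_id: str,
    ion_id: str,
    level: str,
    runs: Sequence[str],
) -> pd.DataFrame:
    """One cross-run ion vector, reindexed to the experiment's run order."""
    sel = (
        (ion_table["precursor_id"] == precursor_id)
        & (ion_table["ion_id"] == ion_id)
        & (ion_table["level"] == level)
    )
    return ion_table.loc[sel].set_index("run_id").reindex(list(runs))
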