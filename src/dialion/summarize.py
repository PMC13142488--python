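"""Median-based summarization: ions -> precursors -> proteins.

The same log-ratio scheme is used at both levels. Feature quantities (ion
vectors, or precursor vectors at the protein level) are log2-transformed and
each feature row is centered by its cross-run mean; per-run medians of the
centered values give robust run-to-run ratios. The absolute level is pinned
by the mean cross-run mean log2 intensity of the three most abundant
features, and results are back-transformed to linear scale. Proteins backed
by fewer than ``min_precursors`` qualified precursors fall back to the
single highest-quality precursor's vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import QuantMatrix
from .lion import ION_KEY

__all__ = [
    "PrecursorQuant",
    "median_summarize",
    "summarize_precursor",
    "summarize_precursors",
    "summarize_protein",
    "build_protein_matrix",
    "DEFAULT_TOP_N",
    "DEFAULT_MIN_PRECURSORS",
]

DEFAULT_TOP_N = 3
DEFAULT_MIN_PRECURSORS = 3


@dataclass
class PrecursorQuant:
    """Per-run quantities of one precursor at the MS1 and/or MS2 level."""

    precursor_id: str
    protein_group: str
    runs: Tuple[str, ...]
    ms1_quant: Optional[np.ndarray] = None
    ms2_quant: Optional[np.ndarray] = None
    mean_quality: float = 0.0
    n_ions_ms1: int = 0
    n_ions_ms2: int = 0

    def __post_init__(self) -> None:
        if self.ms1_quant is None and self.ms2_quant is None:
            raise ValueError(f"{self.precursor_id}: no quantity at either level")

    def vectors_for_mode(self, mode: str) -> List[np.ndarray]:
        if mode == "ms1":
            return [self.ms1_quant] if self.ms1_quant is not None else []
        if mode == "ms2":
            return [self.ms2_quant] if self.ms2_quant is not None else []
        if mode == "integrated":
            return [v for v in (self.ms1_quant, self.ms2_quant) if v is not None]
        raise ValueError(f"unknown mode {mode!r}")


def median_summarize(rows: np.ndarray, top_n: int = DEFAULT_TOP_N) -> np.ndarray:
    """Summarize a (features x runs) matrix of positive linear quantities.

    log2 -> center each row by its mean -> per-run medians -> rescale by the
    mean abundance of the ``top_n`` most abundant rows -> back-transform.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.size == 0:
        raise ValueError("need a non-empty 2-D feature-by-run array")
    if np.any(~np.isfinite(rows)) or np.any(rows <= 0):
        raise ValueError("quantities must be positive and finite (post-inference)")
    log = np.log2(rows)
    row_means = log.mean(axis=1)
    centered = log - row_means[:, None]
    ratios = np.median(centered, axis=0)
    k = min(top_n, len(row_means))
    # most abundant rows by cross-run mean log2 intensity; stable under ties
    top = np.sort(np.argsort(-row_means, kind="stable")[:k])
    abundance = row_means[top].mean()
    return 2.0 ** (abundance + ratios)


def summarize_precursor(ion_rows: np.ndarray, top_n: int = DEFAULT_TOP_N) -> np.ndarray:
    """Per-run precursor quantities from its (ions x runs) intensity matrix."""
    return median_summarize(ion_rows, top_n)


def summarize_precursors(
    ion_table: pd.DataFrame,
    runs: Sequence[str],
    top_n: int = DEFAULT_TOP_N,
) -> List[PrecursorQuant]:
    """Build per-precursor MS1/MS2 quantity vectors from a completed
    (post-LION) ion table."""
    runs = list(runs)
    out: List[PrecursorQuant] = []
    pivot = ion_table.pivot_table(
        index=ION_KEY + ["protein_group"],
        columns="run_id",
        values="quantity",
        sort=False,
    )
    pivot = pivot.reindex(columns=runs)
    qual = ion_table.groupby(ION_KEY, sort=False)["quality"].mean()
    for (pid, pg), sub in pivot.groupby(
        [pivot.index.get_level_values("precursor_id"),
         pivot.index.get_level_values("protein_group")],
        sort=True,
    ):
        levels = sub.index.get_level_values("level")
        quants: Dict[str, Optional[np.ndarray]] = {"ms1": None, "ms2": None}
        n_ions = {"ms1": 0, "ms2": 0}
        for level in ("ms1", "ms2"):
            block = sub.loc[levels == level]
            block = block.dropna(axis=0, how="any")
            if len(block) == 0:
                continue
            quants[level] = summarize_precursor(block.to_numpy(), top_n)
            n_ions[level] = len(block)
        if quants["ms1"] is None and quants["ms2"] is None:
            continue
        ion_quals = qual.loc[
            qual.index.get_level_values("precursor_id") == pid
        ]
        out.append(
            PrecursorQuant(
                precursor_id=pid,
                protein_group=pg,
                runs=tuple(runs),
                ms1_quant=quants["ms1"],
                ms2_quant=quants["ms2"],
                mean_quality=float(ion_quals.mean()) if len(ion_quals) else 0.0,
                n_ions_ms1=n_ions["ms1"],
                n_ions_ms2=n_ions["ms2"],
            )
        )
    return out


def summarize_protein(
    precursors: Sequence[PrecursorQuant],
    mode: str = "integrated",
    min_precursors: int = DEFAULT_MIN_PRECURSORS,
    top_n: int = DEFAULT_TOP_N,
) -> Optional[np.ndarray]:
    """Per-run protein quantities from its precursors.

    In integrated mode each precursor contributes its MS1 and MS2 vectors as
    separate feature rows. With at least ``min_precursors`` feature rows the
    median framework applies; below that, the vector of the precursor with
    the highest mean quality (at the requested mode) is used.
    """
    contributors = [(p, v) for p in precursors for v in p.vectors_for_mode(mode)]
    if not contributors:
        return None
    rows = np.vstack([v for _, v in contributors])
    if len(rows) >= min_precursors:
        return median_summarize(rows, top_n)
    best = max(
        (p for p, _ in contributors),
        key=lambda p: (p.mean_quality, p.precursor_id),
    )
    vecs = best.vectors_for_mode(mode)
    if len(vecs) == 1:
        return vecs[0]
    return median_summarize(np.vstack(vecs), top_n)


def build_protein_matrix(
    precursors: Sequence[PrecursorQuant],
    mode: str = "integrated",
    min_precursors: int = DEFAULT_MIN_PRECURSORS,
    top_n: int = DEFAULT_TOP_N,
) -> QuantMatrix:
    """Assemble the protein-level quantification matrix for one mode."""
    if not precursors:
        return QuantMatrix(values=pd.DataFrame())
    runs = list(precursors[0].runs)
    by_protein: Dict[str, List[PrecursorQuant]] = {}
    for p in precursors:
        by_protein.setdefault(p.protein_group, []).append(p)
    rows = {}
    for pg in sorted(by_protein):
        vec = summarize_protein(by_protein[pg], mode, min_precursors, top_n)
        if vec is not None:
            rows[pg] = vec
    df = pd.DataFrame.from_dict(rows, orient="index", columns=runs)
    return QuantMatrix(values=df)


def precursor_matrix(
    precursors: Sequence[PrecursorQuant], mode: str = "integrated"
) -> QuantMatrix:
    """Precursor-level matrix (integrated mode averages MS1/MS2 rows via the
    median framework per precursor)."""
    if not precursors:
        return QuantMatrix(values=pd.DataFrame())
    runs = list(precursors[0].runs)
    rows = {}
    for p in sorted(precursors, key=lambda q: q.precursor_id):
        vecs = p.vectors_for_mode(mode)
        if not vecs:
            continue
        rows[p.precursor_id] = vecs[0] if len(vecs) == 1 else median_summarize(np.vstack(vecs))
    return QuantMatrix(values=pd.DataFrame.from_dict(rows, orient="index", columns=runs))
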