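"""Core domain types for ion-level DIA quantification.

All intensity quantities are linear-scale and non-negative; retention times
are minutes; ion mobility is inverse reduced mobility (1/K0); m/z is Th.
Missing values are represented as ``None`` (scalars) or ``NaN`` (arrays /
DataFrames) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumRecord",
    "LibraryEntry",
    "IdentificationRecord",
    "SampleMetadata",
    "QuantMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass
class SpectrumRecord:
    """One MS1 or MS2 scan.

    MS2 scans must carry the precursor isolation window
    (``isolation_low`` < ``isolation_high``); MS1 scans must not.
    Peaks are stored as parallel arrays with strictly increasing m/z.
    """

    run_id: str
    ms_level: int
    rt: float
    mz_values: np.ndarray
    intensities: np.ndarray
    im: Optional[float] = None
    isolation_low: Optional[float] = None
    isolation_high: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ms_level not in (1, 2):
            raise ValidationError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.mz_values.shape != self.intensities.shape:
            raise ValidationError("mz_values and intensities must have equal length")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise ValidationError("mz_values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.ms_level == 2:
            if self.isolation_low is None or self.isolation_high is None:
                raise ValidationError("MS2 scan without an isolation window")
            if not self.isolation_low < self.isolation_high:
                raise ValidationError("isolation_low must be < isolation_high")
        elif self.isolation_low is not None or self.isolation_high is not None:
            raise ValidationError("MS1 scan must not carry an isolation window")

    def __eq__(self, other: object) -> bool:  # array fields need np comparison
        if not isinstance(other, SpectrumRecord):
            return NotImplemented
        return (
            self.run_id == other.run_id
            and self.ms_level == other.ms_level
            and np.isclose(self.rt, other.rt)
            and _opt_close(self.im, other.im)
            and _opt_close(self.isolation_low, other.isolation_low)
            and _opt_close(self.isolation_high, other.isolation_high)
            and self.mz_values.shape == other.mz_values.shape
            and np.allclose(self.mz_values, other.mz_values)
            and np.allclose(self.intensities, other.intensities)
        )


def _opt_close(a: Optional[float], b: Optional[float]) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return bool(np.isclose(a, b))


@dataclass(frozen=True)
class LibraryEntry:
    """Spectral-library entry for one precursor (modified sequence + charge).

    ``fragments`` is a tuple of ``(mz, relative_intensity, annotation)``
    sorted by descending relative intensity; only the top six are used for
    MS2 extraction downstream.
    """

    precursor_id: str
    precursor_mz: float
    charge: int
    mono_mass: float
    irt: float
    fragments: tuple
    library_im: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mono_mass <= 0:
            raise ValidationError(f"mono_mass must be > 0 for {self.precursor_id}")
        if self.charge < 1:
            raise ValidationError(f"charge must be >= 1 for {self.precursor_id}")
        if len(self.fragments) < 1:
            raise ValidationError(f"{self.precursor_id}: at least one fragment required")
        rel = [f[1] for f in self.fragments]
        if any(b > a + 1e-12 for a, b in zip(rel, rel[1:])):
            raise ValidationError(
                f"{self.precursor_id}: fragments must be sorted by descending intensity"
            )

    def top_fragments(self, n: int = 6) -> tuple:
        return self.fragments[:n]


@dataclass(frozen=True)
class IdentificationRecord:
    """One precursor identification in one run from an upstream search report."""

    precursor_id: str
    run_id: str
    protein_group: str
    q_value: float
    species: Optional[str] = None
    observed_rt: Optional[float] = None
    observed_im: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(
                f"q_value must be in [0, 1], got {self.q_value} for "
                f"{self.precursor_id}/{self.run_id}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    """Run-to-condition (and optional batch) assignment for one experiment."""

    runs: tuple
    conditions: tuple
    batches: tuple = ()

    def __post_init__(self) -> None:
        if len(self.runs) != len(set(self.runs)):
            raise ValidationError("duplicate run_id in sample metadata")
        if len(self.conditions) != len(self.runs):
            raise ValidationError("conditions must align with runs")
        if self.batches and len(self.batches) != len(self.runs):
            raise ValidationError("batches must align with runs")
        if len(set(self.conditions)) < 1:
            raise ValidationError("at least one condition required")

    @property
    def condition_of(self) -> dict:
        return dict(zip(self.runs, self.conditions))

    def runs_in_condition(self, condition: str) -> list:
        return [r for r, c in zip(self.runs, self.conditions) if c == condition]

    @property
    def condition_names(self) -> list:
        seen: list = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def to_frame(self) -> pd.DataFrame:
        d = {"run_id": self.runs, "condition": self.conditions}
        if self.batches:
            d["batch"] = self.batches
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleMetadata":
        batches = tuple(df["batch"]) if "batch" in df.columns else ()
        return cls(
            runs=tuple(df["run_id"].astype(str)),
            conditions=tuple(df["condition"].astype(str)),
            batches=batches,
        )


@dataclass
class QuantMatrix:
    """Rectangular quantification matrix (rows: proteins or precursors,
    columns: runs). Missing cells are NaN; the finished protein-level matrix
    produced by the full pipeline contains none."""

    values: pd.DataFrame  # index = row ids, columns = run ids

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float, na_value=np.nan)
        if np.any(v[np.isfinite(v)] < 0):
            raise ValidationError("quantities must be non-negative")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def run_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantMatrix):
            return NotImplemented
        if self.row_ids != other.row_ids or self.run_ids != other.run_ids:
            return False
        a = self.values.to_numpy(dtype=float)
        b = other.values.to_numpy(dtype=float)
        # 6-significant-digit agreement (the serialization contract)
        return bool(np.all((np.isnan(a) & np.isnan(b)) | np.isclose(a, b, rtol=5e-6, equal_nan=False)))
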