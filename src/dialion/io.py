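"""Readers and writers for the pipeline's tabular formats and spectra.

Spectra come in two flavours: standard mzML (read-only, via pyteomics) and a
plain-text internal format used for synthetic experiments. The internal
format is a tab-separated scan table — one row per scan with the peak block
inlined as two comma-separated array fields::

    ms_level  rt  im  isolation_low  isolation_high  mz_array  intensity_array

Missing optional fields are empty. The run identity of a spectra file is its
file stem (``runA.scans`` -> ``runA``); metadata keys must match it exactly.

All other inputs/outputs are tab-separated tables:

* identification report: required columns ``precursor_id, run_id,
  protein_group, q_value``; optional ``rt, im, species``. A thin column-name
  mapping for DIA-NN main-report dialects is applied when the canonical
  columns are absent.
* spectral library: ``precursor_id, precursor_mz, charge, mono_mass, irt``
  plus ``fragment_mz`` / ``fragment_intensity`` (semicolon-separated lists)
  and optional ``library_im``, ``fragment_annotation``.
* sample metadata: ``run_id, condition`` and optional ``batch``.
* quantification matrices: first column the row id, one column per run,
  missing cells rendered as empty fields (never 0, so zero intensity stays
  distinguishable from not-quantified).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    IdentificationRecord,
    LibraryEntry,
    QuantMatrix,
    SampleMetadata,
    SpectrumRecord,
    ValidationError,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_identification_report",
    "filter_identification_records",
    "read_library",
    "write_library",
    "read_metadata",
    "write_metadata",
    "read_quant_matrix",
    "write_quant_matrix",
    "write_identification_report",
    "SpectraParseError",
    "SchemaError",
]

PathLike = Union[str, Path]

SCAN_COLUMNS = [
    "ms_level",
    "rt",
    "im",
    "isolation_low",
    "isolation_high",
    "mz_array",
    "intensity_array",
]

# Canonical-column aliases covering common DIA-NN main-report headers.
# Applied only when the canonical name itself is absent; not guaranteed
# against every report-format version.
DIANN_COLUMN_MAP = {
    "precursor_id": ["Precursor.Id", "Modified.Sequence.Charge"],
    "run_id": ["Run", "File.Name"],
    "protein_group": ["Protein.Group", "Protein.Ids"],
    "q_value": ["Q.Value"],
    "rt": ["RT"],
    "im": ["IM"],
    "species": ["Species"],
}


class SpectraParseError(ValidationError):
    """A spectra file could not be parsed; names the first offending scan."""


class SchemaError(ValidationError):
    """A tabular input is missing mandatory columns."""


# ---------------------------------------------------------------------------
# spectra


def _run_id_from_path(path: PathLike) -> str:
    stem = Path(path).stem
    if stem.endswith(".scans"):  # tolerate double extensions like run.scans.tsv
        stem = stem[: -len(".scans")]
    return stem


def read_spectra(path: PathLike, format: str = "internal") -> List[SpectrumRecord]:
    """Read one run's spectra, sorted by (ms_level grouping preserved, rt).

    ``format`` is ``"internal"`` (tab-separated scan table) or ``"mzml"``.
    """
    if format == "internal":
        records = _read_internal(path)
    elif format == "mzml":
        records = _read_mzml(path)
    else:
        raise ValueError(f"unknown spectra format: {format!r}")
    records.sort(key=lambda r: (r.ms_level, -np.inf if r.isolation_low is None else r.isolation_low, r.rt))
    return records


def _read_internal(path: PathLike) -> List[SpectrumRecord]:
    run_id = _run_id_from_path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(
            f"{path}: internal scan table missing columns {missing}"
        )
    records: List[SpectrumRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            mz = _parse_float_list(row.mz_array)
            inten = _parse_float_list(row.intensity_array)
            records.append(
                SpectrumRecord(
                    run_id=run_id,
                    ms_level=int(row.ms_level),
                    rt=float(row.rt),
                    im=float(row.im) if row.im else None,
                    isolation_low=float(row.isolation_low) if row.isolation_low else None,
                    isolation_high=float(row.isolation_high) if row.isolation_high else None,
                    mz_values=mz,
                    intensities=inten,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise SpectraParseError(f"{path}: scan {i}: {exc}") from exc
    return records


def _parse_float_list(s: str) -> np.ndarray:
    if not s:
        return np.empty(0)
    return np.array(s.split(","), dtype=float)


def write_spectra(records: Sequence[SpectrumRecord], path: PathLike) -> None:
    """Write spectra in the internal scan-table format."""
    lines = ["\t".join(SCAN_COLUMNS)]
    fmt = lambda x: "" if x is None else repr(float(x))  # noqa: E731
    for r in records:
        lines.append(
            "\t".join(
                [
                    str(r.ms_level),
                    repr(float(r.rt)),
                    fmt(r.im),
                    fmt(r.isolation_low),
                    fmt(r.isolation_high),
                    ",".join(repr(float(v)) for v in r.mz_values),
                    ",".join(repr(float(v)) for v in r.intensities),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# Read-only mzML parsing via lxml. Controlled-vocabulary terms are matched
# by accession; only the subset this pipeline needs is interpreted (ms level,
# scan start time, isolation window, ion mobility, peak arrays with 32/64-bit
# float encoding, zlib or no compression).

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_INV_MOBILITY = "MS:1002815"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_params(element) -> dict:
    return {
        cv.get("accession"): cv
        for cv in element.iter(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    params = _cv_params(bda)
    node = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _ACC_FLOAT32 in params else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: PathLike) -> List[SpectrumRecord]:
    from lxml import etree

    run_id = _run_id_from_path(path)
    records: List[SpectrumRecord] = []
    tree = etree.parse(str(path))
    for spectrum in tree.iter(f"{_MZML_NS}spectrum"):
        sid = spectrum.get("id", "?")
        try:
            params = _cv_params(spectrum)
            if _ACC_MS_LEVEL not in params:
                raise ValidationError("scan lacks an ms level cvParam")
            level = int(params[_ACC_MS_LEVEL].get("value"))

            rt = None
            im = None
            for scan in spectrum.iter(f"{_MZML_NS}scan"):
                sp = _cv_params(scan)
                if _ACC_SCAN_START in sp:
                    cv = sp[_ACC_SCAN_START]
                    rt = float(cv.get("value"))
                    unit = (cv.get("unitName") or "").lower()
                    if unit.startswith("second") or cv.get("unitAccession") == "UO:0000010":
                        rt /= 60.0
                if _ACC_INV_MOBILITY in sp:
                    im = float(sp[_ACC_INV_MOBILITY].get("value"))
                break
            if rt is None:
                raise ValidationError("scan lacks a scan start time")

            iso_low = iso_high = None
            if level == 2:
                iso = spectrum.find(
                    f"{_MZML_NS}precursorList/{_MZML_NS}precursor/{_MZML_NS}isolationWindow"
                )
                if iso is not None:
                    ip = _cv_params(iso)
                    if _ACC_ISO_TARGET in ip:
                        target = float(ip[_ACC_ISO_TARGET].get("value"))
                        lo = float(ip[_ACC_ISO_LOWER].get("value"))
                        hi = float(ip[_ACC_ISO_UPPER].get("value"))
                        iso_low, iso_high = target - lo, target + hi
                if iso_low is None:
                    raise ValidationError("MS2 scan without isolation window")

            mz = inten = None
            for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
                bp = _cv_params(bda)
                if _ACC_MZ_ARRAY in bp:
                    mz = _decode_binary_array(bda)
                elif _ACC_INT_ARRAY in bp:
                    inten = _decode_binary_array(bda)
            if mz is None or inten is None:
                raise ValidationError("scan lacks m/z or intensity array")
            order = np.argsort(mz, kind="stable")
            records.append(
                SpectrumRecord(
                    run_id=run_id,
                    ms_level=level,
                    rt=rt,
                    im=im,
                    isolation_low=iso_low,
                    isolation_high=iso_high,
                    mz_values=mz[order],
                    intensities=inten[order],
                )
            )
        except (KeyError, ValueError, TypeError, ValidationError) as exc:
            raise SpectraParseError(f"{path}: scan {sid!r}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# identification report

REPORT_REQUIRED = ["precursor_id", "run_id", "protein_group", "q_value"]
REPORT_OPTIONAL = ["rt", "im", "species"]


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for canonical, aliases in DIANN_COLUMN_MAP.items():
        if canonical in df.columns:
            continue
        for alias in aliases:
            if alias in df.columns:
                rename[alias] = canonical
                break
    return df.rename(columns=rename)


def read_identification_report(
    path: PathLike,
    q_threshold: float = 0.01,
    min_runs: int = 3,
) -> List[IdentificationRecord]:
    """Read and filter an identification report.

    Keeps records with ``q_value < q_threshold``, then drops precursors that
    (post q-filter) were identified in fewer than ``min_runs`` distinct runs.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must be in (0, 1]")
    if min_runs < 1:
        raise ValueError("min_runs must be >= 1")
    df = pd.read_csv(path, sep="\t", dtype={"precursor_id": str, "run_id": str})
    df = _canonicalize_columns(df)
    missing = [c for c in REPORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: identification report missing columns {missing}")
    records = [
        IdentificationRecord(
            precursor_id=str(row.precursor_id),
            run_id=str(row.run_id),
            protein_group=str(row.protein_group),
            q_value=float(row.q_value),
            species=_opt_str(getattr(row, "species", None)),
            observed_rt=_opt_float(getattr(row, "rt", None)),
            observed_im=_opt_float(getattr(row, "im", None)),
        )
        for row in df.itertuples(index=False)
    ]
    return filter_identification_records(records, q_threshold, min_runs)


def filter_identification_records(
    records: Iterable[IdentificationRecord],
    q_threshold: float,
    min_runs: int,
) -> List[IdentificationRecord]:
    """Apply the q-value and multi-run filters to in-memory records."""
    passing = [r for r in records if r.q_value < q_threshold]
    runs_per_precursor: dict = {}
    for r in passing:
        runs_per_precursor.setdefault(r.precursor_id, set()).add(r.run_id)
    return [
        r for r in passing if len(runs_per_precursor[r.precursor_id]) >= min_runs
    ]


def write_identification_report(
    records: Sequence[IdentificationRecord], path: PathLike
) -> None:
    df = pd.DataFrame(
        {
            "precursor_id": [r.precursor_id for r in records],
            "run_id": [r.run_id for r in records],
            "protein_group": [r.protein_group for r in records],
            "q_value": [r.q_value for r in records],
            "species": [r.species for r in records],
            "rt": [r.observed_rt for r in records],
            "im": [r.observed_im for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


# ---------------------------------------------------------------------------
# spectral library

LIBRARY_REQUIRED = ["precursor_id", "precursor_mz", "charge", "mono_mass", "irt"]


def read_library(path: PathLike) -> List[LibraryEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"precursor_id": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in LIBRARY_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: spectral library missing columns {missing}")
    if "fragment_mz" not in df.columns or "fragment_intensity" not in df.columns:
        raise SchemaError(f"{path}: spectral library missing fragment columns")
    entries = []
    has_ann = "fragment_annotation" in df.columns
    for row in df.itertuples(index=False):
        mzs = [float(x) for x in str(row.fragment_mz).split(";")]
        intens = [float(x) for x in str(row.fragment_intensity).split(";")]
        anns = (
            str(row.fragment_annotation).split(";")
            if has_ann
            else [f"frag{i+1}" for i in range(len(mzs))]
        )
        frags = tuple(zip(mzs, intens, anns))
        frags = tuple(sorted(frags, key=lambda f: -f[1]))
        entries.append(
            LibraryEntry(
                precursor_id=str(row.precursor_id),
                precursor_mz=float(row.precursor_mz),
                charge=int(row.charge),
                mono_mass=float(row.mono_mass),
                irt=float(row.irt),
                library_im=_opt_float(getattr(row, "library_im", None)),
                fragments=frags,
            )
        )
    return entries


def write_library(entries: Sequence[LibraryEntry], path: PathLike) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "precursor_id": e.precursor_id,
                "precursor_mz": e.precursor_mz,
                "charge": e.charge,
                "mono_mass": e.mono_mass,
                "irt": e.irt,
                "library_im": e.library_im,
                "fragment_mz": ";".join(repr(f[0]) for f in e.fragments),
                "fragment_intensity": ";".join(repr(f[1]) for f in e.fragments),
                "fragment_annotation": ";".join(str(f[2]) for f in e.fragments),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# sample metadata

def read_metadata(path: PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("run_id", "condition") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: sample metadata missing columns {missing}")
    return SampleMetadata.from_frame(df)


def write_metadata(metadata: SampleMetadata, path: PathLike) -> None:
    metadata.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quantification matrices

def write_quant_matrix(matrix: QuantMatrix, path: PathLike, id_column: str = "row_id") -> None:
    """Write a matrix as TSV; missing cells become empty fields and values
    round-trip to 6 significant digits."""
    df = matrix.values.copy()
    df.index.name = id_column
    df.to_csv(path, sep="\t", na_rep="", float_format="%.6g")


def read_quant_matrix(path: PathLike) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return QuantMatrix(values=df.astype(float))
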