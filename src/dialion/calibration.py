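"""Run-specific calibration of library retention time (iRT) and ion
mobility onto observed run coordinates.

Each run gets one monotone map per axis, fitted on anchor precursors —
precursors confidently observed in several runs with low cross-run
coordinate variability. The map is a cubic regression spline with interior
knots at anchor quantiles, isotonized with pool-adjacent-violators so it is
monotone non-decreasing over the anchor range, and continued linearly with
the boundary slope outside it. A seeded 20% holdout yields an RMSE
self-diagnostic per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from sklearn.isotonic import IsotonicRegression

from .model import IdentificationRecord, LibraryEntry, ValidationError

__all__ = [
    "CalibrationModel",
    "CalibrationError",
    "select_anchor_precursors",
    "fit_calibration",
    "build_run_models",
    "predict_missing_coordinates",
    "MIN_ANCHORS",
]

MIN_ANCHORS = 8


class CalibrationError(ValidationError):
    """Calibration impossible for a run/axis (too few or degenerate anchors)."""


@dataclass
class CalibrationModel:
    """Monotone map from library-scale to observed run-scale coordinates."""

    run_id: str
    axis: str  # "rt" or "im"
    anchor_pairs: np.ndarray  # (n, 2): library value, observed value
    grid_x: np.ndarray  # dense grid over the anchor library range
    grid_y: np.ndarray  # isotonized fitted values on grid_x
    rmse_holdout: float

    def predict(self, library_values) -> np.ndarray:
        """Evaluate the fitted map; linear boundary-slope extrapolation
        outside the anchor range."""
        x = np.atleast_1d(np.asarray(library_values, dtype=float))
        y = np.interp(x, self.grid_x, self.grid_y)
        lo, hi = self.grid_x[0], self.grid_x[-1]
        slope_lo = _boundary_slope(self.grid_x, self.grid_y, "low")
        slope_hi = _boundary_slope(self.grid_x, self.grid_y, "high")
        below = x < lo
        above = x > hi
        y[below] = self.grid_y[0] + slope_lo * (x[below] - lo)
        y[above] = self.grid_y[-1] + slope_hi * (x[above] - hi)
        return y if np.ndim(library_values) else float(y[0])

    def __call__(self, library_values):
        return self.predict(library_values)


def _boundary_slope(gx: np.ndarray, gy: np.ndarray, side: str) -> float:
    # secant over the outer 5% of the grid; robust to a flat terminal step
    n = max(2, len(gx) // 20)
    if side == "low":
        dx = gx[n - 1] - gx[0]
        return (gy[n - 1] - gy[0]) / dx if dx > 0 else 0.0
    dx = gx[-1] - gx[-n]
    return (gy[-1] - gy[-n]) / dx if dx > 0 else 0.0


def select_anchor_precursors(
    records: Iterable[IdentificationRecord],
    min_runs: int = 3,
    variability_quantile: float = 0.95,
    axis: str = "rt",
) -> set:
    """Precursors usable as calibration anchors for the given axis.

    A precursor qualifies when it carries an observed coordinate in at least
    ``min_runs`` runs and its cross-run coordinate standard deviation falls
    below the given quantile of all candidates' standard deviations.
    """
    if min_runs < 2:
        raise ValueError("min_runs must be >= 2")
    if not 0 < variability_quantile < 1:
        raise ValueError("variability_quantile must be in (0, 1)")
    attr = "observed_rt" if axis == "rt" else "observed_im"
    values: Dict[str, list] = {}
    for r in records:
        v = getattr(r, attr)
        if v is not None:
            values.setdefault(r.precursor_id, []).append(v)
    candidates = {p: np.std(v) for p, v in values.items() if len(v) >= min_runs}
    if not candidates:
        raise CalibrationError(
            f"no anchor precursor observed in >= {min_runs} runs for axis {axis}"
        )
    sds = np.array(list(candidates.values()))
    cut = np.quantile(sds, variability_quantile)
    return {p for p, sd in candidates.items() if sd <= cut}


def fit_calibration(
    anchors: Sequence[Tuple[float, float]],
    knots: int = 5,
    holdout: float = 0.2,
    seed: int = 0,
    run_id: str = "",
    axis: str = "rt",
) -> CalibrationModel:
    """Fit the monotone spline map from (library, observed) anchor pairs.

    The holdout RMSE is computed by refitting on a seeded 80% of the anchors
    and scoring the remaining 20%; the returned map itself uses all anchors.
    """
    pairs = np.asarray(anchors, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("anchors must be (library, observed) pairs")
    if len(pairs) < MIN_ANCHORS:
        raise CalibrationError(
            f"{run_id}/{axis}: {len(pairs)} anchors < required {MIN_ANCHORS}"
        )
    if np.ptp(pairs[:, 0]) == 0:
        raise CalibrationError(f"{run_id}/{axis}: degenerate constant library values")

    rng = np.random.default_rng(seed)
    n = len(pairs)
    n_test = max(1, int(round(holdout * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    rmse = np.nan
    if len(train_idx) >= MIN_ANCHORS and np.ptp(pairs[train_idx, 0]) > 0:
        gx, gy = _fit_monotone_spline(pairs[train_idx], knots)
        sub = CalibrationModel(run_id, axis, pairs[train_idx], gx, gy, np.nan)
        pred = sub.predict(pairs[test_idx, 0])
        rmse = float(np.sqrt(np.mean((pred - pairs[test_idx, 1]) ** 2)))

    grid_x, grid_y = _fit_monotone_spline(pairs, knots)
    return CalibrationModel(
        run_id=run_id,
        axis=axis,
        anchor_pairs=pairs,
        grid_x=grid_x,
        grid_y=grid_y,
        rmse_holdout=rmse,
    )


def _fit_monotone_spline(pairs: np.ndarray, knots: int) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic regression spline with quantile knots, evaluated on a dense
    grid and isotonized (pool-adjacent-violators) to enforce monotonicity."""
    order = np.argsort(pairs[:, 0], kind="stable")
    x, y = pairs[order, 0], pairs[order, 1]
    # collapse duplicate abscissae (spline fitting needs strictly increasing x)
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.bincount(inverse, weights=y) / np.bincount(inverse)

    grid_x = np.linspace(ux[0], ux[-1], 512)
    if len(ux) <= 4:
        fitted = np.interp(grid_x, ux, uy)
    else:
        n_interior = min(knots, max(0, len(ux) // 4 - 1))
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(ux, qs)
            interior = interior[(interior > ux[0]) & (interior < ux[-1])]
            interior = np.unique(interior)
        else:
            interior = np.array([])
        try:
            spline = LSQUnivariateSpline(ux, uy, interior, k=3)
            fitted = spline(grid_x)
        except ValueError:  # Schoenberg-Whitney violation on clumped anchors
            fitted = np.interp(grid_x, ux, uy)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    grid_y = iso.fit_transform(grid_x, fitted)
    return grid_x, grid_y


def build_run_models(
    records: Sequence[IdentificationRecord],
    library: Dict[str, LibraryEntry],
    axis: str = "rt",
    min_runs: int = 3,
    variability_quantile: float = 0.95,
    knots: int = 5,
    holdout: float = 0.2,
    seed: int = 0,
) -> Dict[str, CalibrationModel]:
    """One calibration model per run for the given axis."""
    anchors_set = select_anchor_precursors(records, min_runs, variability_quantile, axis)
    attr = "observed_rt" if axis == "rt" else "observed_im"
    lib_attr = "irt" if axis == "rt" else "library_im"
    per_run: Dict[str, list] = {}
    for r in records:
        obs = getattr(r, attr)
        if obs is None or r.precursor_id not in anchors_set:
            continue
        entry = library.get(r.precursor_id)
        if entry is None:
            continue
        lib_val = getattr(entry, lib_attr)
        if lib_val is None:
            continue
        per_run.setdefault(r.run_id, []).append((lib_val, obs))
    models = {}
    for run_id, pairs in sorted(per_run.items()):
        models[run_id] = fit_calibration(
            pairs, knots=knots, holdout=holdout, seed=seed, run_id=run_id, axis=axis
        )
    return models


def predict_missing_coordinates(
    records: Sequence[IdentificationRecord],
    library: Dict[str, LibraryEntry],
    rt_models: Dict[str, CalibrationModel],
    im_models: Optional[Dict[str, CalibrationModel]] = None,
    all_runs: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, float]:
    """Assign an RT (and IM when modeled) to every (precursor, run) pair.

    The precursor set is expanded across ``all_runs`` (default: the runs seen
    in the records) so that precursors identified in a subset of runs still
    get extraction coordinates everywhere. Observed values are never
    overwritten; each coordinate is flagged observed or inferred. Returns the
    coordinate table and the fraction of inferred RT coordinates.
    """
    runs = list(all_runs) if all_runs is not None else sorted({r.run_id for r in records})
    observed: Dict[Tuple[str, str], IdentificationRecord] = {}
    precursor_protein: Dict[str, str] = {}
    precursor_species: Dict[str, Optional[str]] = {}
    for r in records:
        observed[(r.precursor_id, r.run_id)] = r
        precursor_protein[r.precursor_id] = r.protein_group
        precursor_species.setdefault(r.precursor_id, r.species)

    with_im = im_models is not None and len(im_models) > 0
    rows = []
    n_inferred = 0
    skipped = []
    for pid in sorted(precursor_protein):
        entry = library.get(pid)
        for run in runs:
            rec = observed.get((pid, run))
            rt = rec.observed_rt if rec is not None else None
            im = rec.observed_im if rec is not None else None
            rt_inferred = False
            im_inferred = False
            if rt is None:
                if entry is None:
                    skipped.append(pid)
                    continue
                model = rt_models.get(run)
                if model is None:
                    raise CalibrationError(f"no RT model for run {run}")
                rt = float(model.predict(entry.irt))
                rt_inferred = True
                n_inferred += 1
            if with_im and im is None:
                if entry is not None and entry.library_im is not None:
                    model = im_models.get(run)
                    if model is None:
                        raise CalibrationError(f"no IM model for run {run}")
                    im = float(model.predict(entry.library_im))
                    im_inferred = True
            rows.append(
                {
                    "precursor_id": pid,
                    "run_id": run,
                    "protein_group": precursor_protein[pid],
                    "species": precursor_species[pid],
                    "rt": rt,
                    "im": im,
                    "rt_inferred": rt_inferred,
                    "im_inferred": im_inferred,
                }
            )
    if skipped:
        import warnings

        warnings.warn(
            f"{len(set(skipped))} precursors absent from library; skipped",
            stacklevel=2,
        )
    coords = pd.DataFrame(rows)
    inferred_fraction = n_inferred / len(coords) if len(coords) else 0.0
    return coords, inferred_fraction
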