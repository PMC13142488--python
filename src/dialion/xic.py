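"""Extracted-ion-chromatogram engine.

For each precursor in each run, XICs are pulled from MS1 spectra (the
monoisotopic peak and its observable isotope peaks) and from MS2 spectra of
the matching isolation window (the top library fragments). One representative
elution profile per precursor-run is chosen by a composite of three scores —
similarity to sibling XICs, conformity to a Gaussian-like peak with balanced
signal around the apex, and integrated intensity — and annotated with a
refined apex and an FWHM. Every ion is then integrated over
[apex - FWHM, apex + FWHM], with interference truncated against the
representative profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import SpectrumRecord

__all__ = [
    "XICTrace",
    "XICScore",
    "RunSpectraIndex",
    "extract_xic",
    "correlation_score",
    "shape_score",
    "select_representative",
    "integrate_and_truncate",
    "DEFAULT_WEIGHTS",
]

#: composite weights (correlation, shape, intensity)
DEFAULT_WEIGHTS = (0.4, 0.4, 0.2)


@dataclass
class XICTrace:
    """One ion's intensity-vs-time trace in one run."""

    run_id: str
    precursor_id: str
    ion_id: str  # "MS1:k" or "MS2:frag_j"
    level: str  # "ms1" | "ms2"
    times: np.ndarray
    intensities: np.ndarray
    apex_time: Optional[float] = None
    fwhm: Optional[float] = None
    quality: Optional[float] = None
    raw_quantity: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class XICScore:
    correlation_score: float
    shape_score: float
    intensity_score: float
    composite: float


# ---------------------------------------------------------------------------
# extraction


class RunSpectraIndex:
    """Peak index over one run's spectra for fast repeated XIC extraction.

    Scans are grouped into MS1 and per-isolation-window MS2 groups; within a
    group, all peaks are pooled into one m/z-sorted array carrying their scan
    index, so one target query is a binary search plus a scatter-add.
    """

    def __init__(self, spectra: Sequence[SpectrumRecord]):
        self.run_id = spectra[0].run_id if spectra else ""
        groups: Dict[Tuple, List[SpectrumRecord]] = {}
        for s in spectra:
            key = ("ms1",) if s.ms_level == 1 else ("ms2", s.isolation_low, s.isolation_high)
            groups.setdefault(key, []).append(s)
        self._groups = {}
        for key, scans in groups.items():
            scans.sort(key=lambda s: s.rt)
            rts = np.array([s.rt for s in scans])
            ims = np.array(
                [s.im if s.im is not None else np.nan for s in scans]
            )
            counts = [len(s.mz_values) for s in scans]
            mz = np.concatenate([s.mz_values for s in scans]) if scans else np.empty(0)
            inten = np.concatenate([s.intensities for s in scans]) if scans else np.empty(0)
            scan_idx = np.repeat(np.arange(len(scans)), counts)
            order = np.argsort(mz, kind="stable")
            self._groups[key] = (rts, ims, mz[order], inten[order], scan_idx[order])

    def ms2_group_key(self, precursor_mz: float):
        for key in self._groups:
            if key[0] == "ms2" and key[1] <= precursor_mz < key[2]:
                return key
        return None

    def extract(
        self,
        target_mz: float,
        tol_ppm: float,
        rt_center: float,
        rt_halfwidth: float,
        level: str = "ms1",
        precursor_mz: Optional[float] = None,
        im_center: Optional[float] = None,
        im_halfwidth: Optional[float] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Return (times, intensities) over scans in the RT/IM window; scans
        with no matching peak contribute zero intensity."""
        if level == "ms1":
            key = ("ms1",)
        else:
            if precursor_mz is None:
                raise ValueError("MS2 extraction requires precursor_mz")
            key = self.ms2_group_key(precursor_mz)
        if key is None or key not in self._groups:
            return np.empty(0), np.empty(0)
        rts, ims, mz, inten, scan_idx = self._groups[key]
        in_rt = (rts >= rt_center - rt_halfwidth) & (rts <= rt_center + rt_halfwidth)
        if im_center is not None and im_halfwidth is not None:
            with np.errstate(invalid="ignore"):
                in_im = np.abs(ims - im_center) <= im_halfwidth
            in_rt &= np.where(np.isnan(ims), True, in_im)
        sel = np.nonzero(in_rt)[0]
        if sel.size == 0:
            return np.empty(0), np.empty(0)
        tol = target_mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz, target_mz - tol, side="left")
        hi = np.searchsorted(mz, target_mz + tol, side="right")
        per_scan = np.zeros(len(rts))
        np.add.at(per_scan, scan_idx[lo:hi], inten[lo:hi])
        return rts[sel], per_scan[sel]


def extract_xic(
    spectra: Sequence[SpectrumRecord],
    target_mz: float,
    tol_ppm: float,
    rt_center: float,
    rt_halfwidth: float,
    level: str = "ms1",
    precursor_mz: Optional[float] = None,
    im_center: Optional[float] = None,
    im_halfwidth: Optional[float] = None,
    precursor_id: str = "",
    ion_id: str = "",
) -> XICTrace:
    """Extract one XIC from a list of scans (convenience wrapper over
    :class:`RunSpectraIndex` for one-off queries)."""
    index = RunSpectraIndex(list(spectra))
    t, y = index.extract(
        target_mz, tol_ppm, rt_center, rt_halfwidth, level,
        precursor_mz, im_center, im_halfwidth,
    )
    return XICTrace(
        run_id=index.run_id,
        precursor_id=precursor_id,
        ion_id=ion_id or f"{level.upper()}:{target_mz:.4f}",
        level=level,
        times=t,
        intensities=y,
    )


# ---------------------------------------------------------------------------
# scoring


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or len(a) != len(b):
        return 0.0
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _common_grid(a: XICTrace, b: XICTrace) -> Tuple[np.ndarray, np.ndarray]:
    if len(a) == len(b) and np.allclose(a.times, b.times):
        return a.intensities, b.intensities
    common, ia, ib = np.intersect1d(
        np.round(a.times, 9), np.round(b.times, 9), return_indices=True
    )
    return a.intensities[ia], b.intensities[ib]


def correlation_score(trace: XICTrace, peers: Sequence[XICTrace]) -> float:
    """Mean Pearson correlation to sibling XICs on the shared time grid.
    Traces shorter than 3 points and zero-variance pairs score 0."""
    if len(trace) < 3 or not peers:
        return 0.0
    rs = []
    for p in peers:
        ya, yb = _common_grid(trace, p)
        rs.append(_pearson(ya, yb))
    return float(np.mean(rs))


def _correlation_scores(traces: Sequence[XICTrace]) -> np.ndarray:
    """Per-candidate mean peer correlation; vectorized when all candidates
    share one time grid (the common case within a precursor-run)."""
    n = len(traces)
    if n < 2:
        return np.zeros(n)
    lengths = {len(tr) for tr in traces}
    if len(lengths) == 1 and lengths != {0}:
        t0 = traces[0].times
        if all(np.array_equal(tr.times, t0) for tr in traces[1:]) and len(t0) >= 3:
            y = np.vstack([tr.intensities for tr in traces])
            sd = y.std(axis=1)
            ok = sd > 0
            r = np.zeros((n, n))
            if ok.sum() >= 2:
                sub = np.corrcoef(y[ok])
                r[np.ix_(ok, ok)] = np.nan_to_num(sub)
            np.fill_diagonal(r, 0.0)
            return r.sum(axis=1) / (n - 1)
    return np.array(
        [
            correlation_score(tr, [p for j, p in enumerate(traces) if j != i])
            for i, tr in enumerate(traces)
        ]
    )


def shape_score(trace: XICTrace) -> float:
    """Gaussian conformity times apex balance, in [0, 1].

    ``r+`` is the clipped Pearson correlation between the trace and a
    moment-matched Gaussian; the balance term ``b = 1 - |L - R|/(L + R)``
    compares integrated signal left and right of the apex.
    """
    y = trace.intensities
    t = trace.times
    if len(y) < 5:
        return 0.0
    total = y.sum()
    if total <= 0:
        return 0.0
    w = y / total
    mu = float(np.sum(w * t))
    sd = float(np.sqrt(np.sum(w * (t - mu) ** 2)))
    if sd == 0:
        return 0.0
    gauss = np.exp(-0.5 * ((t - mu) / sd) ** 2)
    r_plus = max(0.0, _pearson(y, gauss))
    apex = int(np.argmax(y))
    left = float(np.trapezoid(y[: apex + 1], t[: apex + 1])) if apex > 0 else 0.0
    right = float(np.trapezoid(y[apex:], t[apex:])) if apex < len(y) - 1 else 0.0
    if left + right <= 0:
        return 0.0
    balance = 1.0 - abs(left - right) / (left + right)
    return r_plus * balance


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    if len(y) < window:
        return y.copy()
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    # fix edge normalization of the 'same' convolution
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return out / norm


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-grid apex (time, height) via a 3-point parabola around index i."""
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = 0.5 * (y0 - y2) / denom
            dt = 0.5 * (t[i + 1] - t[i - 1])
            return float(t[i] + d * dt), float(y1 - 0.25 * (y0 - y2) * d)
    return float(t[i]), float(y[i])


def _half_crossing(
    t: np.ndarray, y: np.ndarray, apex_idx: int, half: float, side: str
) -> Optional[float]:
    if side == "left":
        for j in range(apex_idx, 0, -1):
            if y[j - 1] < half <= y[j]:
                return float(
                    t[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (t[j] - t[j - 1])
                )
    else:
        for j in range(apex_idx, len(y) - 1):
            if y[j + 1] < half <= y[j]:
                return float(
                    t[j] + (y[j] - half) / (y[j] - y[j + 1]) * (t[j + 1] - t[j])
                )
    return None


def estimate_apex_fwhm(trace: XICTrace) -> Tuple[float, float]:
    """Apex time (on the smoothed profile, parabolically refined) and FWHM
    (half-height crossings of the raw profile by linear interpolation).

    When only one side crosses half height, the crossed side is reflected;
    when neither does, FWHM falls back to half the trace span.
    """
    t, y = trace.times, trace.intensities
    smoothed = _smooth(y)
    apex_idx = int(np.argmax(smoothed))
    apex_time, _ = _parabolic_apex(t, smoothed, apex_idx)
    raw_idx = int(np.argmax(y))
    _, apex_height = _parabolic_apex(t, y, raw_idx)
    half = apex_height / 2.0
    left = _half_crossing(t, y, raw_idx, half, "left")
    right = _half_crossing(t, y, raw_idx, half, "right")
    apex_t_raw, _ = _parabolic_apex(t, y, raw_idx)
    if left is not None and right is not None:
        fwhm = right - left
    elif left is not None:
        fwhm = 2.0 * (apex_t_raw - left)
    elif right is not None:
        fwhm = 2.0 * (right - apex_t_raw)
    else:
        fwhm = (t[-1] - t[0]) / 2.0 if len(t) > 1 else 1.0
    return apex_time, max(fwhm, 1e-9)


def _rank_percentile(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    n = len(values)
    if n == 1:
        return np.ones(1)
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def score_candidates(
    traces: Sequence[XICTrace],
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> List[XICScore]:
    """Composite scores for all candidate XICs of one precursor-run.

    Correlation is mapped from [-1, 1] to [0, 1]; intensity is the rank
    percentile of the integrated raw signal among the candidates.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    w_c, w_s, w_i = weights
    corr = _correlation_scores(traces)
    shape = np.array([shape_score(tr) for tr in traces])
    raw_area = np.array(
        [
            float(np.trapezoid(tr.intensities, tr.times)) if len(tr) > 1 else 0.0
            for tr in traces
        ]
    )
    inten_norm = _rank_percentile(raw_area)
    corr_norm = (corr + 1.0) / 2.0
    composite = w_c * corr_norm + w_s * shape + w_i * inten_norm
    return [
        XICScore(float(c), float(s), float(a), float(comp))
        for c, s, a, comp in zip(corr, shape, raw_area, composite)
    ]


def select_representative(
    traces: Sequence[XICTrace],
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
    min_shape: float = 0.5,
    min_apex_intensity: float = 0.0,
) -> Optional[XICTrace]:
    """Pick the representative elution profile for one precursor-run.

    Candidates are ranked by composite score (ties broken by ion_id); the
    first whose shape score passes ``min_shape`` and whose raw apex intensity
    passes ``min_apex_intensity`` is returned, annotated with apex and FWHM.
    Returns None when no candidate qualifies — the precursor-run is then
    treated as missing.
    """
    candidates = [tr for tr in traces if len(tr) >= 5]
    if not candidates:
        return None
    scores = score_candidates(candidates, weights)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i].composite, candidates[i].ion_id),
    )
    for i in order:
        tr = candidates[i]
        if scores[i].shape_score < min_shape:
            continue
        smoothed = _smooth(tr.intensities)
        apex_idx = int(np.argmax(smoothed))
        if tr.intensities[apex_idx] < min_apex_intensity or tr.intensities[apex_idx] <= 0:
            continue
        apex_time, fwhm = estimate_apex_fwhm(tr)
        return replace(tr, apex_time=apex_time, fwhm=fwhm)
    return None


# ---------------------------------------------------------------------------
# quantification


def truncate_window(
    trace: XICTrace,
    representative: XICTrace,
    level_scale: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Windowed, interference-truncated view of one ion's trace.

    Restricts the trace to [apex - FWHM, apex + FWHM] of the representative
    (adding interpolated samples at the exact window edges), computes the
    XIC-quality score (clipped Pearson correlation to the representative
    inside the window), and truncates points exceeding ``level_scale`` times
    the expected profile — the representative scaled by the median near-apex
    trace/representative intensity ratio.

    Returns ``(times, clipped_intensities, quality)``.
    """
    if representative.apex_time is None or representative.fwhm is None:
        raise ValueError("representative must carry apex_time and fwhm")
    apex, fwhm = representative.apex_time, representative.fwhm
    lo, hi = apex - fwhm, apex + fwhm
    mask = (trace.times >= lo) & (trace.times <= hi)
    t = trace.times[mask]
    y = trace.intensities[mask].astype(float)
    if t.size == 0:
        return t, y, 0.0
    # interpolated samples at the exact window edges so the trapezoid
    # covers the full [apex - FWHM, apex + FWHM] span
    if trace.times[0] < lo < t[0]:
        t = np.insert(t, 0, lo)
        y = np.insert(y, 0, np.interp(lo, trace.times, trace.intensities))
    if t[-1] < hi < trace.times[-1]:
        t = np.append(t, hi)
        y = np.append(y, np.interp(hi, trace.times, trace.intensities))
    rep_y = np.interp(t, representative.times, representative.intensities)
    quality = max(0.0, _pearson(y, rep_y))

    near = np.abs(t - apex) <= fwhm / 2.0
    rep_near = rep_y[near]
    obs_near = y[near]
    pos = rep_near > 0
    if np.any(pos):
        ratio = float(np.median(obs_near[pos] / rep_near[pos]))
        bound = level_scale * rep_y * ratio
        y = np.minimum(y, bound)
    return t, y, quality


def integrate_and_truncate(
    trace: XICTrace,
    representative: XICTrace,
    level_scale: float = 3.0,
) -> Tuple[float, float]:
    """Integrate one ion over the representative's quantification window.

    Truncates interference via :func:`truncate_window`, then takes the
    trapezoidal integral of the clipped trace as the raw quantity.
    Returns ``(raw_quantity, quality)``; an empty window yields ``(0, 0)``.
    """
    t, y, quality = truncate_window(trace, representative, level_scale)
    raw_quantity = float(np.trapezoid(y, t)) if t.size > 1 else 0.0
    return raw_quantity, quality
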