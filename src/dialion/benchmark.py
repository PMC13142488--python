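"""Differential-abundance analysis and two-proteome benchmark metrics.

The benchmark design is an HYE-style mixture: one species is held constant
between conditions (expected unchanged), one is spiked up and one down, so
species labels provide ground truth for differential abundance. Proteins
passing the quantifiable filter are tested with an empirical-Bayes moderated
t-test (limma-style variance shrinkage, re-implemented here so the pipeline
is self-contained), and calls at |log2FC| > 0.5 and BH-adjusted P < 0.05 are
scored against the expected per-species direction. Metrics: empirical
differential-abundance FDR daFDR = FP / (FP + TP), partial AUC of the ROC at
FPR <= 0.1, per-group CV profiles and per-species fold-change error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests

from .model import QuantMatrix, SampleMetadata

__all__ = [
    "BenchmarkResult",
    "filter_quantifiable",
    "moderated_test",
    "classify_daps",
    "roc_pauc",
    "quant_metrics",
    "species_from_protein_group",
    "DEFAULT_FC_CUT",
    "DEFAULT_P_CUT",
    "DEFAULT_FPR_MAX",
]

DEFAULT_FC_CUT = 0.5
DEFAULT_P_CUT = 0.05
DEFAULT_FPR_MAX = 0.1

#: UniProt-style suffixes used when no explicit species column is given.
SPECIES_SUFFIXES = ("HUMAN", "YEAST", "ECOLI")


@dataclass
class BenchmarkResult:
    """Confusion counts and benchmark metrics against species ground truth."""

    table: pd.DataFrame  # per protein: log2fc, raw_p, adj_p, species, call
    tp: int
    fp: int
    tn: int
    fn: int
    dafdr: float
    pauc: Optional[float] = None
    cv_profile: Optional[pd.DataFrame] = None
    fold_change_error: Optional[pd.Series] = None

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def species_from_protein_group(protein_group: str) -> Optional[str]:
    """Infer the species label from a UniProt-style protein-group suffix
    (e.g. ``ALBU_HUMAN`` -> ``HUMAN``)."""
    tail = protein_group.rsplit("_", 1)
    if len(tail) == 2 and tail[1].upper() in SPECIES_SUFFIXES:
        return tail[1].upper()
    return None


def filter_quantifiable(
    matrix: QuantMatrix,
    metadata: SampleMetadata,
    min_valid_per_group: int = 5,
    min_precursors: int = 2,
    precursor_counts: Optional[Dict[str, int]] = None,
) -> QuantMatrix:
    """Keep proteins with enough valid values in every group and enough
    supporting precursors.

    ``min_valid_per_group`` mirrors dataset completeness presets such as
    5-of-8, 3-of-3, 3-of-6 or 5-of-15 replicates per sample group.
    """
    if min_valid_per_group < 1 or min_precursors < 1:
        raise ValueError("thresholds must be >= 1")
    df = matrix.values
    keep = pd.Series(True, index=df.index)
    for condition in metadata.condition_names:
        runs = [r for r in metadata.runs_in_condition(condition) if r in df.columns]
        keep &= df[runs].notna().sum(axis=1) >= min_valid_per_group
    if precursor_counts is not None:
        counts = pd.Series(precursor_counts).reindex(df.index).fillna(0)
        keep &= counts >= min_precursors
    return QuantMatrix(values=df.loc[keep])


# ---------------------------------------------------------------------------
# moderated t-test (empirical-Bayes variance shrinkage)


def _fit_f_dist(s2: np.ndarray, df_resid: float) -> Tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) from the
    observed residual variances, via the moments of log s^2."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    if len(z) < 2:
        val = float(np.exp(z.mean())) if len(z) else 1e-12
        return np.inf, val
    e = z.mean() - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    v = z.var(ddof=1) - special.polygamma(1, df_resid / 2.0)
    if v <= 0:
        return np.inf, float(np.exp(e))
    # invert trigamma(d0/2) = v
    def f(x):
        return special.polygamma(1, x) - v

    try:
        half_d0 = optimize.brentq(f, 1e-8, 1e8)
    except ValueError:
        return np.inf, float(np.exp(e))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_test(
    log2_matrix: QuantMatrix,
    metadata: SampleMetadata,
    prior_df: Optional[float] = None,
    use_moderation: bool = True,
) -> pd.DataFrame:
    """Two-condition moderated t-test on a log2-scale matrix.

    Per protein: ``log2fc = mean(group A) - mean(group B)`` (A and B in
    metadata condition order); the t denominator uses the posterior variance
    ``(d0*s0^2 + d*s^2)/(d0 + d)`` with prior (d0, s0^2) estimated by method
    of moments across proteins. ``prior_df`` overrides the estimated d0;
    ``use_moderation=False`` gives the ordinary Welch t-test cross-check.
    Returns a DataFrame with columns log2fc, raw_p, adj_p (BH).
    """
    conditions = metadata.condition_names
    if len(conditions) != 2:
        raise ValueError("moderated_test requires exactly 2 conditions")
    df = log2_matrix.values
    runs_a = [r for r in metadata.runs_in_condition(conditions[0]) if r in df.columns]
    runs_b = [r for r in metadata.runs_in_condition(conditions[1]) if r in df.columns]
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("need >= 2 samples per condition")
    a = df[runs_a].to_numpy(dtype=float)
    b = df[runs_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    log2fc = mean_a - mean_b

    if not use_moderation:
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        raw_p = np.asarray(p, dtype=float)
    else:
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
        d = na + nb - 2
        s2 = ((na - 1) * var_a + (nb - 1) * var_b) / d
        if np.all(s2 <= 0):
            import warnings

            warnings.warn(
                "zero within-group variance everywhere; using epsilon variance",
                stacklevel=2,
            )
            s2 = np.full_like(s2, 1e-12)
        if prior_df is None:
            d0, s0_sq = _fit_f_dist(s2[s2 > 0], d)
        else:
            d0 = prior_df
            s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1e-12
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        se = np.where(se > 0, se, np.sqrt(1e-12))
        t = log2fc / se
        if np.isinf(df_total):
            raw_p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            raw_p = 2.0 * stats.t.sf(np.abs(t), df_total)

    adj_p = multipletests(raw_p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "raw_p": raw_p, "adj_p": adj_p}, index=df.index
    )


# ---------------------------------------------------------------------------
# ground-truth scoring


def classify_daps(
    results: pd.DataFrame,
    species_truth: Dict[str, str],  # species -> "up" | "down" | "unchanged"
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    species: Optional[pd.Series] = None,
) -> BenchmarkResult:
    """Score differential-abundance calls against species ground truth.

    A protein is called differentially abundant when |log2fc| > ``fc_cut``
    and adj_p < ``p_cut``. Calls in the expected direction are TPs; calls in
    the wrong direction or among expected-unchanged species are FPs;
    missed expected-changing proteins are FNs; quiet unchanged ones TNs.
    """
    tab = results.copy()
    if species is not None:
        tab["species"] = species
    elif "species" not in tab.columns:
        tab["species"] = [species_from_protein_group(i) for i in tab.index]
    if tab["species"].isna().any():
        missing = tab.index[tab["species"].isna()].tolist()[:5]
        raise ValueError(f"proteins without species label, e.g. {missing}")

    expected = tab["species"].map(species_truth)
    if expected.isna().any():
        raise ValueError("species_truth must cover every species present")
    significant = (tab["adj_p"] < p_cut) & (tab["log2fc"].abs() > fc_cut)
    direction = np.where(tab["log2fc"] > 0, "up", "down")
    calls = []
    for sig, exp, direc in zip(significant, expected, direction):
        if sig:
            calls.append("TP" if (exp in ("up", "down") and direc == exp) else "FP")
        else:
            calls.append("TN" if exp == "unchanged" else "FN")
    tab["call"] = calls
    counts = pd.Series(calls).value_counts()
    tp, fp = int(counts.get("TP", 0)), int(counts.get("FP", 0))
    tn, fn = int(counts.get("TN", 0)), int(counts.get("FN", 0))
    dafdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    return BenchmarkResult(table=tab, tp=tp, fp=fp, tn=tn, fn=fn, dafdr=dafdr)


def roc_pauc(
    results: pd.DataFrame,
    species_truth: Dict[str, str],
    fpr_max: float = DEFAULT_FPR_MAX,
    species: Optional[pd.Series] = None,
) -> float:
    """Unnormalized partial AUC of the ROC restricted to FPR <= ``fpr_max``.

    Positives are proteins of expected-changing species, negatives those of
    unchanged species; the ranking is adjusted P ascending with ties broken
    by |log2fc| descending. Range [0, fpr_max]; a perfect ranking scores
    ``fpr_max`` and a diagonal ROC ``fpr_max**2 / 2``.
    """
    tab = results.copy()
    if species is not None:
        tab["species"] = species
    elif "species" not in tab.columns:
        tab["species"] = [species_from_protein_group(i) for i in tab.index]
    expected = tab["species"].map(species_truth)
    is_pos = expected.isin(["up", "down"]).to_numpy()
    is_neg = (expected == "unchanged").to_numpy()
    n_pos, n_neg = int(is_pos.sum()), int(is_neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need >= 1 positive and >= 1 negative protein")
    # composite ranking score: smaller is better
    rank_key = list(zip(tab["adj_p"].to_numpy(), -tab["log2fc"].abs().to_numpy()))
    order = sorted(range(len(tab)), key=lambda i: rank_key[i])
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and rank_key[order[j]] == rank_key[order[i]]:
            j += 1
        for k in order[i:j]:  # tied block advances diagonally
            if is_pos[k]:
                tp += 1
            elif is_neg[k]:
                fp += 1
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    fpr_arr, tpr_arr = np.array(fpr), np.array(tpr)
    if fpr_arr[-1] < fpr_max:
        fpr_arr = np.append(fpr_arr, fpr_max)
        tpr_arr = np.append(tpr_arr, tpr_arr[-1])
    tpr_at_max = np.interp(fpr_max, fpr_arr, tpr_arr)
    mask = fpr_arr <= fpr_max
    xs = np.append(fpr_arr[mask], fpr_max)
    ys = np.append(tpr_arr[mask], tpr_at_max)
    return float(np.trapezoid(ys, xs))


def quant_metrics(
    matrix: QuantMatrix,
    metadata: SampleMetadata,
    expected_log2fc: Dict[str, float],
    species: Optional[pd.Series] = None,
) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """CV profiles and fold-change errors on a linear-scale matrix.

    Returns ``(cv_profile, fold_change_error, per_protein_log2fc)``:
    cv_profile has one row per protein with the CV (%) per group;
    fold_change_error is the per-species median |observed - expected| log2
    fold change between the two conditions (A over B in metadata order).
    """
    conditions = metadata.condition_names
    if len(conditions) != 2:
        raise ValueError("quant_metrics requires exactly 2 conditions")
    df = matrix.values
    if species is None:
        species = pd.Series(
            [species_from_protein_group(i) for i in df.index], index=df.index
        )
    cv = {}
    means = {}
    for condition in conditions:
        runs = [r for r in metadata.runs_in_condition(condition) if r in df.columns]
        sub = df[runs].to_numpy(dtype=float)
        m = np.nanmean(sub, axis=1)
        sd = np.nanstd(sub, axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv[condition] = np.where(m > 0, sd / m * 100.0, np.nan)
        means[condition] = m
    cv_profile = pd.DataFrame(cv, index=df.index)
    cv_profile["species"] = species
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_fc = np.log2(means[conditions[0]] / means[conditions[1]])
    obs_fc = pd.Series(obs_fc, index=df.index)
    dev = (obs_fc - species.map(expected_log2fc)).abs()
    fold_change_error = dev.groupby(species).median()
    return cv_profile, fold_change_error, obs_fc
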