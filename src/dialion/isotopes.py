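"""Poisson-averagine estimate of the observable isotopic envelope.

For a peptide of monoisotopic mass *m* (Da), the expected number of heavy
isotope substitutions is approximated as lambda = 0.00052 * m, and the
relative abundances of the M+0, M+1, ... peaks follow the Poisson pmf.
Peaks whose pmf is at least 10% of the envelope's mode are considered
observable on a typical DIA instrument; the observable count always starts
at M+0 and runs through the highest peak satisfying the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IsotopeEnvelope",
    "LAMBDA_COEFF",
    "ISOTOPE_DELTA",
    "OBSERVABILITY_THRESHOLD",
    "count_observable_isotopes",
    "ms1_target_mz_list",
    "isotope_envelope",
]

#: Heavy-isotope rate per Dalton of peptide mass (averagine approximation).
LAMBDA_COEFF = 0.00052
#: Average 13C-12C isotope spacing in Da.
ISOTOPE_DELTA = 1.0033548
#: Observability cutoff relative to the envelope mode.
OBSERVABILITY_THRESHOLD = 0.10


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Observable isotope peaks of one precursor at its charge state."""

    mono_mass: float
    lam: float
    probs: np.ndarray  # Poisson pmf for k = 0..n_observable-1
    n_observable: int
    target_mzs: np.ndarray  # m/z of M+0 .. M+(n_observable-1)

    @property
    def relative_heights(self) -> np.ndarray:
        """Peak heights normalized so the tallest observable peak is 1."""
        return self.probs / self.probs.max()


def count_observable_isotopes(
    mono_mass: float,
    threshold: float = OBSERVABILITY_THRESHOLD,
    lambda_coeff: float = LAMBDA_COEFF,
) -> int:
    """Number of observable isotope peaks (M+0 through the highest peak with
    pmf >= ``threshold`` x the envelope mode). Always >= 1."""
    if mono_mass <= 0:
        raise ValueError(f"mono_mass must be positive, got {mono_mass}")
    lam = lambda_coeff * mono_mass
    # The pmf is unimodal; this range safely covers mode and threshold tail.
    kmax = int(np.ceil(lam + 10.0 * np.sqrt(lam) + 10.0))
    k = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(k, lam)
    cutoff = threshold * pmf.max()
    qualifying = np.nonzero(pmf >= cutoff)[0]
    return int(qualifying.max()) + 1 if qualifying.size else 1


def ms1_target_mz_list(
    precursor_mz: float,
    charge: int,
    n_observable: int,
    delta: float = ISOTOPE_DELTA,
) -> np.ndarray:
    """m/z targets of M+0 .. M+(n_observable-1) at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if n_observable < 1:
        raise ValueError("n_observable must be >= 1")
    return precursor_mz + np.arange(n_observable) * (delta / charge)


def isotope_envelope(
    mono_mass: float,
    precursor_mz: float,
    charge: int,
    threshold: float = OBSERVABILITY_THRESHOLD,
    lambda_coeff: float = LAMBDA_COEFF,
    delta: float = ISOTOPE_DELTA,
) -> IsotopeEnvelope:
    """Full observable envelope: count, pmf values and MS1 target m/z list."""
    n = count_observable_isotopes(mono_mass, threshold, lambda_coeff)
    lam = lambda_coeff * mono_mass
    probs = stats.poisson.pmf(np.arange(n), lam)
    return IsotopeEnvelope(
        mono_mass=mono_mass,
        lam=lam,
        probs=probs,
        n_observable=n,
        target_mzs=ms1_target_mz_list(precursor_mz, charge, n, delta),
    )
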