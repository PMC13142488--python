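"""Ground-truthed synthetic DIA experiments.

Emulates a two-condition HYE-style species mixture: human-like proteins
unchanged between conditions, yeast-like up, E. coli-like down. Each protein
carries a handful of precursors; each precursor elutes as a Gaussian peak,
shows a Poisson-consistent isotope envelope in MS1 and six library fragments
in its isolation window in MS2. Noise is multiplicative log-normal, and
whole-ion-per-run dropout follows a logistic curve in log10 intensity so
that missingness concentrates at low abundance — the regime the
neighborhood-minimum inference is designed for.

Precursor and fragment m/z values are laid out on jittered grids with
collision-free spacing (relative to the extraction tolerance), so traces are
interference-free by default; ``interference_rate`` adds contaminant peaks
for stress tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .isotopes import isotope_envelope
from .model import (
    IdentificationRecord,
    LibraryEntry,
    SampleMetadata,
    SpectrumRecord,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_experiment", "render_spectra", "write_experiment"]

PROTON = 1.007276


@dataclass
class SyntheticConfig:
    """Study design and signal model of one synthetic experiment.

    Defaults describe the benchmark condition used throughout the test
    suite: 300 proteins over three species, two conditions with four
    replicates each, 2x up / 4x down spike ratios (smallest expected
    |log2FC| of 1), a 10-minute gradient with 0.05-min elution peaks, 10%
    multiplicative noise and intensity-dependent ion dropout averaging
    roughly 15-20% of ion-run observations.
    """

    seed: int
    n_proteins: Dict[str, int] = field(
        default_factory=lambda: {"HUMAN": 150, "YEAST": 75, "ECOLI": 75}
    )
    fold_changes: Dict[str, float] = field(
        default_factory=lambda: {"HUMAN": 1.0, "YEAST": 2.0, "ECOLI": 0.25}
    )
    precursors_per_protein: Tuple[int, int] = (2, 3)
    replicates: int = 4
    conditions: Tuple[str, str] = ("A", "B")
    abundance_log10_mean: float = 5.0
    abundance_log10_sd: float = 0.6
    share_log10_sd: float = 0.3
    elution_sigma_min: float = 0.05
    noise_cv: float = 0.10
    low_intensity_extra_cv: float = 0.40
    scan_noise_cv: float = 0.05
    scan_noise_low_extra_cv: float = 0.60
    detectability_log10_sd: float = 0.50
    suppression_prob_max: float = 0.30
    suppression_slope: float = 2.5
    suppression_factor: float = 0.1
    suppression_log_sd: float = 0.7
    suppression_dropout: float = 0.85
    dropout_max: float = 0.06
    dropout_midpoint_log10: float = 3.8
    dropout_slope: float = 6.0
    rt_gradient_min: float = 10.0
    cycle_min: float = 0.02
    rt_report_sd_min: float = 0.01
    coordinate_deletion_fraction: float = 0.15
    window_low: float = 400.0
    window_high: float = 1000.0
    window_width: float = 25.0
    n_fragments: int = 6
    interference_rate: float = 0.0
    include_im: bool = False
    q_value_range: Tuple[float, float] = (1e-4, 5e-3)

    def run_ids(self) -> List[str]:
        return [
            f"run_{c}{i+1}" for c in self.conditions for i in range(self.replicates)
        ]

    def metadata(self) -> SampleMetadata:
        runs = self.run_ids()
        conds = [r.split("_")[1][0] for r in runs]
        return SampleMetadata(runs=tuple(runs), conditions=tuple(conds))


@dataclass
class GroundTruth:
    """Everything the generator knows; regenerable bit-identically from the
    config (the generator is a pure function of config + seed)."""

    proteins: pd.DataFrame  # protein_group, species, abund_A, abund_B
    precursors: pd.DataFrame  # precursor_id, protein_group, species, charge,
    # mono_mass, precursor_mz, irt, sigma_min, share
    ions: pd.DataFrame  # precursor_id, ion_id, level, target_mz, rel_intensity
    ion_runs: pd.DataFrame  # precursor_id, ion_id, level, run_id, amplitude,
    # true_quantity, dropped
    rt_truth: pd.DataFrame  # precursor_id, run_id, true_rt, reported

    def expected_log2fc(self, fold_changes: Dict[str, float]) -> Dict[str, float]:
        return {sp: math.log2(fc) for sp, fc in fold_changes.items()}


def _run_warp_params(rng: np.random.Generator, n_runs: int) -> List[Tuple[float, float]]:
    offsets = rng.normal(0.0, 0.05, n_runs)
    slopes = 1.0 + rng.normal(0.0, 0.01, n_runs)
    return list(zip(offsets, slopes))


def _warp(irt: np.ndarray, offset: float, slope: float, gradient: float) -> np.ndarray:
    base = gradient * irt / 100.0
    return offset + slope * base + 0.15 * np.sin(irt / 12.0)


#: fraction of a Gaussian's area inside +-FWHM of the apex
#: (window half-width = one full FWHM = 2*sqrt(2 ln 2) sigma)
_WINDOW_AREA = math.erf(2.0 * math.sqrt(2.0 * math.log(2.0)) / math.sqrt(2.0))


def true_window_integral(amplitude: float, sigma_min: float) -> float:
    """Noise-free integral of a Gaussian ion peak over [apex-FWHM, apex+FWHM],
    the pipeline's quantification window."""
    return amplitude * sigma_min * math.sqrt(2.0 * math.pi) * _WINDOW_AREA


def generate_experiment(
    config: SyntheticConfig,
) -> Tuple[List[LibraryEntry], List[IdentificationRecord], SampleMetadata, GroundTruth]:
    """Sample the full ground truth and the derived library/report tables."""
    rng = np.random.default_rng(config.seed)
    metadata = config.metadata()
    runs = list(metadata.runs)
    n_runs = len(runs)

    # --- proteins -----------------------------------------------------------
    prot_rows = []
    for species in sorted(config.n_proteins):
        for i in range(config.n_proteins[species]):
            base = 10.0 ** rng.normal(
                config.abundance_log10_mean, config.abundance_log10_sd
            )
            fc = config.fold_changes[species]
            prot_rows.append(
                {
                    "protein_group": f"P{len(prot_rows):04d}_{species}",
                    "species": species,
                    "abund_A": base * fc,
                    "abund_B": base,
                }
            )
    proteins = pd.DataFrame(prot_rows)

    # --- precursors ---------------------------------------------------------
    lo, hi = config.precursors_per_protein
    n_prec_per = rng.integers(lo, hi + 1, size=len(proteins))
    n_precursors = int(n_prec_per.sum())

    # jittered collision-free m/z grid inside the isolation-window span
    span_lo, span_hi = config.window_low + 20.0, config.window_high - 20.0
    spacing = min(0.8, (span_hi - span_lo) / (1.3 * n_precursors))
    grid = np.arange(span_lo, span_hi, spacing)
    mz_choices = rng.choice(len(grid), size=n_precursors, replace=False)
    prec_mz = grid[mz_choices] + rng.uniform(-0.02, 0.02, n_precursors)

    prec_rows = []
    k = 0
    for (_, prot), n_prec in zip(proteins.iterrows(), n_prec_per):
        for j in range(n_prec):
            charge = int(rng.choice([2, 3]))
            mz = float(prec_mz[k])
            mono_mass = charge * (mz - PROTON)
            prec_rows.append(
                {
                    "precursor_id": f"PEP{k:05d}/{charge}",
                    "protein_group": prot.protein_group,
                    "species": prot.species,
                    "charge": charge,
                    "mono_mass": mono_mass,
                    "precursor_mz": mz,
                    "irt": float(rng.uniform(2.0, 98.0)),
                    "sigma_min": float(
                        config.elution_sigma_min * rng.uniform(0.85, 1.15)
                    ),
                    "share": 10.0 ** rng.normal(-0.4, config.share_log10_sd),
                }
            )
            k += 1
    precursors = pd.DataFrame(prec_rows)

    # --- ions: MS1 isotope peaks + MS2 fragments ---------------------------
    edges = np.arange(config.window_low, config.window_high + 1e-9, config.window_width)
    frag_grid_spacing = 0.35
    frag_grid = np.arange(200.0, 1500.0, frag_grid_spacing)
    win_index = np.clip(
        np.searchsorted(edges, precursors["precursor_mz"], side="right") - 1,
        0,
        len(edges) - 2,
    )
    ion_rows = []
    lib_entries = []
    frag_used: Dict[int, set] = {}
    for idx, prec in precursors.iterrows():
        env = isotope_envelope(prec.mono_mass, prec.precursor_mz, prec.charge)
        heights = env.relative_heights
        for k_iso, (mz, h) in enumerate(zip(env.target_mzs, heights)):
            ion_rows.append(
                {
                    "precursor_id": prec.precursor_id,
                    "ion_id": f"MS1:{k_iso}",
                    "level": "ms1",
                    "target_mz": float(mz),
                    "rel_intensity": float(h),
                }
            )
        w = int(win_index[idx])
        used = frag_used.setdefault(w, set())
        frag_mzs = []
        while len(frag_mzs) < config.n_fragments:
            cand = int(rng.integers(0, len(frag_grid)))
            if cand not in used:
                used.add(cand)
                frag_mzs.append(frag_grid[cand] + float(rng.uniform(-0.05, 0.05)))
        rel = np.sort(rng.uniform(0.2, 1.0, config.n_fragments))[::-1]
        rel = rel / rel[0]
        frags = []
        for j, (fmz, fr) in enumerate(zip(frag_mzs, rel)):
            ion_rows.append(
                {
                    "precursor_id": prec.precursor_id,
                    "ion_id": f"MS2:frag_{j+1}",
                    "level": "ms2",
                    "target_mz": float(fmz),
                    "rel_intensity": float(fr),
                }
            )
            frags.append((float(fmz), float(fr), f"frag_{j+1}"))
        lib_entries.append(
            LibraryEntry(
                precursor_id=prec.precursor_id,
                precursor_mz=float(prec.precursor_mz),
                charge=int(prec.charge),
                mono_mass=float(prec.mono_mass),
                irt=float(prec.irt),
                library_im=float(0.7 + 0.0005 * prec.precursor_mz)
                if config.include_im
                else None,
                fragments=tuple(frags),
            )
        )
    ions = pd.DataFrame(ion_rows)

    # --- per-run truth: RT warps, amplitudes, dropout ----------------------
    warps = _run_warp_params(rng, n_runs)
    irt = precursors["irt"].to_numpy()
    rt_rows = []
    true_rts = np.empty((len(precursors), n_runs))
    for r, (run, (off, slope)) in enumerate(zip(runs, warps)):
        true_rts[:, r] = _warp(irt, off, slope, config.rt_gradient_min)
    deleted = rng.random((len(precursors), n_runs)) < config.coordinate_deletion_fraction
    for i, prec in precursors.iterrows():
        for r, run in enumerate(runs):
            rt_rows.append(
                {
                    "precursor_id": prec.precursor_id,
                    "run_id": run,
                    "true_rt": float(true_rts[i, r]),
                    "reported": not bool(deleted[i, r]),
                }
            )
    rt_truth = pd.DataFrame(rt_rows)

    cond_abund = {
        config.conditions[0]: proteins.set_index("protein_group")["abund_A"],
        config.conditions[1]: proteins.set_index("protein_group")["abund_B"],
    }
    cond_of_run = metadata.condition_of

    merged = ions.merge(
        precursors[["precursor_id", "protein_group", "share", "sigma_min"]],
        on="precursor_id",
    )
    n_ion = len(merged)
    amp_base = np.empty((n_ion, n_runs))
    for r, run in enumerate(runs):
        abund = cond_abund[cond_of_run[run]].loc[merged["protein_group"]].to_numpy()
        amp_base[:, r] = abund * merged["share"].to_numpy() * merged["rel_intensity"].to_numpy()
    log_base = np.log10(np.maximum(amp_base, 1e-30))
    # heteroscedastic multiplicative noise: low-abundance ions are noisier
    # (shot-noise-like), the regime where dropout concentrates
    cv = config.noise_cv + config.low_intensity_extra_cv / (
        1.0 + np.exp(config.dropout_slope * (log_base - config.dropout_midpoint_log10))
    )
    sigma_noise = np.sqrt(np.log(1.0 + cv**2))
    noise = np.exp(rng.normal(0.0, 1.0, size=(n_ion, n_runs)) * sigma_noise)
    amplitude = amp_base * noise
    # per-ion detectability offset: some ions ionize/transfer poorly for
    # their abundance, making missingness partly ion-idiosyncratic rather
    # than perfectly correlated within a precursor
    detectability = rng.normal(0.0, config.detectability_log10_sd, n_ion)
    log_eff = log_base + detectability[:, None]
    # sporadic signal suppression at low effective intensity: a heavy lower
    # tail of strongly attenuated measurements (ionization/sampling loss).
    # Suppression is the dominant cause of dropout — a suppressed ion-run
    # usually falls below detection, so a missing entry's true signal is
    # typically far below the same-condition observed minimum, while the
    # surviving measurements stay essentially unbiased. Suppressed runs
    # that do get detected are low-S/N and are rendered with ragged
    # profiles (see render_spectra), so the XIC-quality rule flags them.
    p_supp = config.suppression_prob_max / (
        1.0 + np.exp(config.suppression_slope * (log_eff - config.dropout_midpoint_log10))
    )
    suppressed = rng.random((n_ion, n_runs)) < p_supp
    supp_factor = np.exp(
        rng.normal(np.log(config.suppression_factor), config.suppression_log_sd,
                   size=(n_ion, n_runs))
    )
    amplitude = np.where(suppressed, amplitude * supp_factor, amplitude)
    # residual whole-ion-per-run dropout driven by effective intensity,
    # increasing as intensity decreases
    p_drop = np.where(
        suppressed,
        config.suppression_dropout,
        config.dropout_max
        / (1.0 + np.exp(config.dropout_slope * (log_eff - config.dropout_midpoint_log10))),
    )
    dropped = rng.random((n_ion, n_runs)) < p_drop

    sig = merged["sigma_min"].to_numpy()
    ir_rows = []
    for r, run in enumerate(runs):
        ir_rows.append(
            pd.DataFrame(
                {
                    "precursor_id": merged["precursor_id"],
                    "ion_id": merged["ion_id"],
                    "level": merged["level"],
                    "run_id": run,
                    "amplitude": amplitude[:, r],
                    "true_quantity": [
                        true_window_integral(a, s) for a, s in zip(amp_base[:, r], sig)
                    ],
                    "dropped": dropped[:, r],
                }
            )
        )
    ion_runs = pd.concat(ir_rows, ignore_index=True)

    # --- identification report ---------------------------------------------
    id_records = []
    q_lo, q_hi = config.q_value_range
    for i, prec in precursors.iterrows():
        for r, run in enumerate(runs):
            rt_obs = (
                None
                if deleted[i, r]
                else float(true_rts[i, r] + rng.normal(0.0, config.rt_report_sd_min))
            )
            im_obs = (
                float(0.7 + 0.0005 * prec.precursor_mz + rng.normal(0.0, 0.002))
                if config.include_im and not deleted[i, r]
                else None
            )
            id_records.append(
                IdentificationRecord(
                    precursor_id=prec.precursor_id,
                    run_id=run,
                    protein_group=prec.protein_group,
                    q_value=float(rng.uniform(q_lo, q_hi)),
                    species=prec.species,
                    observed_rt=rt_obs,
                    observed_im=im_obs,
                )
            )

    truth = GroundTruth(
        proteins=proteins,
        precursors=precursors,
        ions=ions,
        ion_runs=ion_runs,
        rt_truth=rt_truth,
    )
    return lib_entries, id_records, metadata, truth


def render_spectra(
    truth: GroundTruth, config: SyntheticConfig
) -> Dict[str, List[SpectrumRecord]]:
    """Render per-run MS1/MS2 scans from the ground truth.

    MS1 scans carry each surviving precursor's isotope peaks as Gaussians in
    time; MS2 scans carry its fragments in the matching isolation window.
    Scan-level multiplicative noise is applied per peak; dropout removes the
    whole ion from a run. All 25-m/z windows are scanned every cycle, so
    empty scans exist and extracted traces see explicit zeros.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of truth draws
    runs = config.run_ids()
    cycles = np.arange(0.0, config.rt_gradient_min + config.cycle_min / 2, config.cycle_min)
    n_cyc = len(cycles)
    edges = np.arange(config.window_low, config.window_high + 1e-9, config.window_width)
    n_win = len(edges) - 1

    def scan_sigma_for(amplitude: float) -> float:
        # scan-to-scan noise grows as the realized signal approaches the
        # detection floor (low S/N), which degrades the XIC-quality score of
        # barely detected (e.g. suppressed-but-surviving) ion-runs
        cv = config.scan_noise_cv + config.scan_noise_low_extra_cv / (
            1.0
            + math.exp(
                2.0
                * (math.log10(max(amplitude, 1e-30)) - config.dropout_midpoint_log10)
            )
        )
        return math.sqrt(math.log(1.0 + cv**2))

    # flatten all per-ion metadata into plain arrays once, joined to ion_runs
    ion_full = truth.ion_runs.merge(
        truth.ions[["precursor_id", "ion_id", "target_mz"]],
        on=["precursor_id", "ion_id"],
    ).merge(
        truth.precursors[["precursor_id", "sigma_min", "precursor_mz"]],
        on="precursor_id",
    ).merge(
        truth.rt_truth[["precursor_id", "run_id", "true_rt"]],
        on=["precursor_id", "run_id"],
    )

    out: Dict[str, List[SpectrumRecord]] = {}
    for run in runs:
        sub = ion_full[(ion_full["run_id"] == run) & (~ion_full["dropped"])]
        # accumulators: group id 0 = MS1, 1..n_win = isolation windows
        acc_cycle: List[List[np.ndarray]] = [[] for _ in range(n_win + 1)]
        acc_mz: List[List[np.ndarray]] = [[] for _ in range(n_win + 1)]
        acc_int: List[List[np.ndarray]] = [[] for _ in range(n_win + 1)]
        amps = sub["amplitude"].to_numpy()
        rts = sub["true_rt"].to_numpy()
        sigmas = sub["sigma_min"].to_numpy()
        target_mzs = sub["target_mz"].to_numpy()
        is_ms1 = (sub["level"] == "ms1").to_numpy()
        wins = np.clip(
            np.searchsorted(edges, sub["precursor_mz"].to_numpy(), side="right") - 1,
            0,
            n_win - 1,
        )
        for amp, rt, sigma, tmz, ms1_flag, w in zip(
            amps, rts, sigmas, target_mzs, is_ms1, wins
        ):
            i_lo = max(0, int(np.searchsorted(cycles, rt - 4 * sigma)))
            i_hi = min(n_cyc, int(np.searchsorted(cycles, rt + 4 * sigma)))
            if i_hi <= i_lo:
                continue
            t = cycles[i_lo:i_hi]
            profile = amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
            profile = profile * np.exp(rng.normal(0.0, scan_sigma_for(amp), len(t)))
            g = 0 if ms1_flag else int(w) + 1
            acc_cycle[g].append(np.arange(i_lo, i_hi))
            acc_mz[g].append(np.full(i_hi - i_lo, tmz))
            acc_int[g].append(profile)

        if config.interference_rate > 0:
            _add_interference(rng, config, cycles, acc_cycle, acc_mz, acc_int, n_win, edges)

        records: List[SpectrumRecord] = []
        for g in range(n_win + 1):
            if acc_cycle[g]:
                c = np.concatenate(acc_cycle[g])
                m = np.concatenate(acc_mz[g])
                y = np.concatenate(acc_int[g])
                order = np.lexsort((m, c))
                c, m, y = c[order], m[order], y[order]
                bounds = np.searchsorted(c, np.arange(n_cyc + 1))
            else:
                c = m = y = np.empty(0)
                bounds = np.zeros(n_cyc + 1, dtype=int)
            iso_low = None if g == 0 else float(edges[g - 1])
            iso_high = None if g == 0 else float(edges[g])
            level = 1 if g == 0 else 2
            for ci in range(n_cyc):
                s, e = bounds[ci], bounds[ci + 1]
                mz_s, int_s = m[s:e], y[s:e]
                if len(mz_s) > 1:
                    umz, inv = np.unique(mz_s, return_inverse=True)
                    if len(umz) < len(mz_s):
                        int_s = np.bincount(inv, weights=int_s)
                        mz_s = umz
                records.append(
                    SpectrumRecord(
                        run_id=run,
                        ms_level=level,
                        rt=float(cycles[ci]),
                        isolation_low=iso_low,
                        isolation_high=iso_high,
                        mz_values=mz_s,
                        intensities=int_s,
                    )
                )
        out[run] = records
    return out


def _add_interference(rng, config, cycles, acc_cycle, acc_mz, acc_int, n_win, edges):
    """Contaminant peaks for stress tests: random co-eluting signals."""
    n = int(config.interference_rate * len(cycles))
    for g in range(n_win + 1):
        for _ in range(n):
            ci = int(rng.integers(0, len(cycles)))
            width = int(rng.integers(3, 15))
            hi = min(len(cycles), ci + width)
            mz = float(rng.uniform(200.0, 1500.0) if g else rng.uniform(config.window_low, config.window_high))
            amp = 10.0 ** rng.uniform(3.0, 6.0)
            idx = np.arange(ci, hi)
            acc_cycle[g].append(idx)
            acc_mz[g].append(np.full(len(idx), mz))
            acc_int[g].append(np.full(len(idx), amp))


def write_experiment(
    out_dir,
    library: Sequence[LibraryEntry],
    records: Sequence[IdentificationRecord],
    metadata: SampleMetadata,
    truth: GroundTruth,
    spectra: Dict[str, List[SpectrumRecord]],
) -> None:
    """Write a self-contained experiment directory (library.tsv, report.tsv,
    metadata.tsv, spectra/*.scans, truth/*.tsv)."""
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    dio.write_library(library, out / "library.tsv")
    dio.write_identification_report(records, out / "report.tsv")
    dio.write_metadata(metadata, out / "metadata.tsv")
    for run, scans in spectra.items():
        dio.write_spectra(scans, out / "spectra" / f"{run}.scans")
    truth.proteins.to_csv(out / "truth" / "proteins.tsv", sep="\t", index=False)
    truth.precursors.to_csv(out / "truth" / "precursors.tsv", sep="\t", index=False)
    truth.ions.to_csv(out / "truth" / "ions.tsv", sep="\t", index=False)
    truth.ion_runs.to_csv(out / "truth" / "ion_runs.tsv", sep="\t", index=False)
    truth.rt_truth.to_csv(out / "truth" / "rt_truth.tsv", sep="\t", index=False)
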