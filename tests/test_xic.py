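"""XIC extraction, scoring, representative selection and integration."""

import numpy as np
import pytest

from dialion.model import SpectrumRecord
from dialion.xic import (
    truncate_window,
    XICTrace,
    correlation_score,
    estimate_apex_fwhm,
    extract_xic,
    integrate_and_truncate,
    select_representative,
    shape_score,
)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _trace(times, intensities, ion_id="MS1:0", level="ms1", **kw):
    return XICTrace(
        run_id="r", precursor_id="P", ion_id=ion_id, level=level,
        times=np.asarray(times, float), intensities=np.asarray(intensities, float),
        **kw,
    )


def _gauss_trace(sigma=0.1, apex=5.0, amp=1000.0, dt=0.02, span=4.0, **kw):
    t = np.arange(apex - span * sigma, apex + span * sigma + dt / 2, dt)
    return _trace(t, amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2), **kw)


class TestExtraction:
    def _scan(self, rt, peaks, level=1, iso=None):
        mz = sorted(p[0] for p in peaks)
        inten = [dict(peaks)[m] for m in mz]
        kw = {}
        if level == 2:
            kw = {"isolation_low": iso[0], "isolation_high": iso[1]}
        return SpectrumRecord(
            run_id="r", ms_level=level, rt=rt, mz_values=mz, intensities=inten, **kw
        )

    def test_peak_within_tolerance(self):
        spectra = [self._scan(1.0, [(500.000, 1000.0)])]
        tr = extract_xic(spectra, 500.000, 15.0, 1.0, 0.5)
        np.testing.assert_allclose(tr.times, [1.0])
        np.testing.assert_allclose(tr.intensities, [1000.0])

    def test_peak_outside_tolerance_gives_zero(self):
        # 500.020 sits 40 ppm from the 500.000 peak; 15 ppm misses it
        spectra = [self._scan(1.0, [(500.000, 1000.0)])]
        tr = extract_xic(spectra, 500.020, 15.0, 1.0, 0.5)
        np.testing.assert_allclose(tr.intensities, [0.0])

    def test_isolation_filter_excludes_scan(self):
        spectra = [self._scan(1.0, [(310.0, 50.0)], level=2, iso=(400.0, 425.0))]
        tr = extract_xic(spectra, 310.0, 15.0, 1.0, 0.5, level="ms2", precursor_mz=450.0)
        assert len(tr) == 0

    def test_empty_rt_window(self):
        spectra = [self._scan(10.0, [(500.0, 1.0)])]
        tr = extract_xic(spectra, 500.0, 15.0, 1.0, 0.5)
        assert len(tr) == 0

    def test_multiple_matching_peaks_summed(self):
        spectra = [self._scan(1.0, [(499.999, 300.0), (500.001, 200.0)])]
        tr = extract_xic(spectra, 500.000, 15.0, 1.0, 0.5)
        np.testing.assert_allclose(tr.intensities, [500.0])


class TestCorrelationScore:
    def test_identical_peers(self):
        g = _gauss_trace()
        assert correlation_score(g, [g, g, g]) == pytest.approx(1.0)

    def test_mirrored_pair_matches_hand_pearson(self):
        t = np.linspace(0, 1, 11)
        a = np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2)
        b = a.max() - a  # inverted profile
        r_hand = np.corrcoef(a, b)[0, 1]
        score = correlation_score(_trace(t, a), [_trace(t, b)])
        assert score == pytest.approx(r_hand)
        assert score == pytest.approx(-1.0)

    def test_constant_trace_scores_zero(self):
        t = np.linspace(0, 1, 11)
        assert correlation_score(_trace(t, np.full(11, 5.0)), [_gauss_trace()]) == 0.0

    def test_short_trace_scores_zero(self):
        assert correlation_score(_trace([0, 1], [1, 2]), [_trace([0, 1], [1, 2])]) == 0.0


class TestShapeScore:
    def test_clean_gaussian_near_one(self):
        t = np.linspace(-3, 3, 21)
        tr = _trace(t, np.exp(-0.5 * t**2))
        assert shape_score(tr) >= 0.99

    def test_monotone_ramp_penalized(self):
        tr = _trace(np.arange(11.0), np.arange(11.0))
        assert shape_score(tr) < 0.5

    def test_all_zero_trace(self):
        assert shape_score(_trace(np.arange(10.0), np.zeros(10))) == 0.0


class TestApexFwhm:
    @pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0, 10.0, 20.0])
    def test_gaussian_closed_form(self, sigma):
        t = np.arange(0.0, 16 * sigma + 1)
        apex = 8 * sigma + 0.3  # off-grid apex
        tr = _trace(t, 500.0 * np.exp(-0.5 * ((t - apex) / sigma) ** 2))
        apex_est, fwhm = estimate_apex_fwhm(tr)
        assert fwhm == pytest.approx(GAUSS_FWHM * sigma, rel=0.02)
        assert apex_est == pytest.approx(apex, abs=0.5)

    def test_one_sided_fallback_reflects(self):
        # right half of a Gaussian only: left crossing never reached
        sigma = 3.0
        t = np.arange(0.0, 5 * sigma)
        tr = _trace(t, 100.0 * np.exp(-0.5 * (t / sigma) ** 2))
        _, fwhm = estimate_apex_fwhm(tr)
        assert fwhm == pytest.approx(GAUSS_FWHM * sigma, rel=0.25)


class TestSelectRepresentative:
    def test_single_gaussian_annotated(self):
        tr = _gauss_trace(sigma=0.1)
        rep = select_representative([tr])
        assert rep is not None
        assert rep.fwhm == pytest.approx(GAUSS_FWHM * 0.1, rel=0.05)
        assert rep.apex_time == pytest.approx(5.0, abs=0.02)

    def test_gaussian_beats_noise(self):
        rng = np.random.default_rng(0)
        g = _gauss_trace(ion_id="MS1:0")
        noise = _trace(g.times, rng.uniform(0, 50, len(g)), ion_id="MS2:frag_1")
        rep = select_representative([noise, g])
        assert rep is not None
        assert rep.ion_id == "MS1:0"

    def test_apex_intensity_threshold(self):
        tr = _gauss_trace(amp=5.0)
        assert select_representative([tr], min_apex_intensity=10.0) is None

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(4)
        traces = [
            _gauss_trace(amp=100 * (i + 1), ion_id=f"MS2:frag_{i+1}")
            for i in range(4)
        ]
        for tr in traces:
            tr.intensities = tr.intensities + rng.normal(0, 1.0, len(tr))
        winner = select_representative(traces).ion_id
        perm = [traces[i] for i in rng.permutation(4)]
        assert select_representative(perm).ion_id == winner


class TestIntegrateTruncate:
    def _rep(self, times, intensities, apex, fwhm):
        return _trace(times, intensities, apex_time=apex, fwhm=fwhm)

    def test_constant_trace_trapezoid(self):
        t = np.arange(0.0, 11.0)
        rep = self._rep(t, np.full(11, 10.0), apex=5.0, fwhm=4.0)
        tr = _trace(t, np.full(11, 10.0))
        q, _ = integrate_and_truncate(tr, rep, level_scale=3.0)
        assert q == pytest.approx(80.0)  # constant 10 over window span 8

    def test_identity_quality_one_no_clipping(self):
        g = _gauss_trace(sigma=0.1)
        apex, fwhm = 5.0, GAUSS_FWHM * 0.1
        rep = self._rep(g.times, g.intensities, apex, fwhm)
        q, quality = integrate_and_truncate(g, rep, level_scale=2.0)
        quality_free, _ = integrate_and_truncate(g, rep, level_scale=1e9)
        assert quality == pytest.approx(1.0)
        assert q == pytest.approx(quality_free)

    def test_spike_clipped(self):
        g = _gauss_trace(sigma=0.1)
        apex, fwhm = 5.0, GAUSS_FWHM * 0.1
        rep = self._rep(g.times, g.intensities.copy(), apex, fwhm)
        spiked = _trace(g.times, g.intensities.copy())
        i_spike = np.argmin(np.abs(spiked.times - apex + fwhm / 3))
        spiked.intensities[i_spike] *= 100.0
        q_clip, _ = integrate_and_truncate(spiked, rep, level_scale=2.0)
        q_raw, _ = integrate_and_truncate(spiked, rep, level_scale=1e9)
        assert q_clip < q_raw
        # clipped integral close to the spike-free one
        q_clean, _ = integrate_and_truncate(g, rep, level_scale=2.0)
        assert q_clip < 1.5 * q_clean

    def test_truncation_never_increases_and_idempotent(self):
        rng = np.random.default_rng(11)
        g = _gauss_trace(sigma=0.1)
        apex, fwhm = 5.0, GAUSS_FWHM * 0.1
        rep = self._rep(g.times, g.intensities.copy(), apex, fwhm)
        for _ in range(25):
            y = g.intensities * np.exp(rng.normal(0, 0.05, len(g)))
            n_spike = rng.integers(1, 3)  # spikes on a minority of points
            idx = rng.choice(len(g), n_spike, replace=False)
            y[idx] *= rng.uniform(3, 50, n_spike)
            tr = _trace(g.times, y)
            q_unclipped, _ = integrate_and_truncate(tr, rep, level_scale=1e9)
            q1, _ = integrate_and_truncate(tr, rep, level_scale=2.0)
            assert q1 <= q_unclipped + 1e-9
            # idempotence: re-truncating the clipped trace changes nothing
            t1, y1, _ = truncate_window(tr, rep, level_scale=2.0)
            t2, y2, _ = truncate_window(_trace(t1, y1), rep, level_scale=2.0)
            np.testing.assert_allclose(y2, y1, rtol=1e-12)
            q2, _ = integrate_and_truncate(_trace(t1, y1), rep, level_scale=2.0)
            assert q2 == pytest.approx(q1, rel=1e-9)

    def test_integration_linear_in_scale(self):
        g = _gauss_trace(sigma=0.1)
        rep = self._rep(g.times, g.intensities.copy(), 5.0, GAUSS_FWHM * 0.1)
        q1, _ = integrate_and_truncate(g, rep, level_scale=3.0)
        g3 = _trace(g.times, 3.0 * g.intensities)
        q3, _ = integrate_and_truncate(g3, rep, level_scale=3.0)
        assert q3 == pytest.approx(3.0 * q1)

    def test_empty_window(self):
        t = np.arange(0.0, 5.0)
        rep = self._rep(t, np.ones(5), apex=20.0, fwhm=1.0)
        q, quality = integrate_and_truncate(_trace(t, np.ones(5)), rep, 3.0)
        assert (q, quality) == (0.0, 0.0)
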