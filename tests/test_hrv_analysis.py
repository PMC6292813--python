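"""Tests of HRV metrics, outlier clusters, rate response and overdrive recovery."""

import numpy as np
import pytest

from biopace.hrv_analysis import (
    RrSeries,
    corrected_recovery_time,
    detect_outlier_clusters,
    hrv_metrics,
    rate_response,
    rr_from_signal,
)
from biopace.synthetic_data import RrGenConfig, SignalTemplateConfig, gen_rr, gen_signal


def brute_force_metrics(rr):
    """Independent definitional computation (plain loops)."""
    n = len(rr)
    mean = sum(rr) / n
    sdrr = (sum((x - mean) ** 2 for x in rr) / (n - 1)) ** 0.5
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    # geometric SD1: rotate the (RR[n], RR[n+1]) cloud by -45 degrees
    pts = [((rr[i + 1] - rr[i]) / 2 ** 0.5) for i in range(n - 1)]
    pm = sum(pts) / len(pts)
    sd1 = (sum((p - pm) ** 2 for p in pts) / (len(pts) - 1)) ** 0.5
    return sdrr, rmssd, sd1


class TestHrvMetrics:
    def test_constant_series_all_zero(self):
        m = hrv_metrics(RrSeries(rr=np.full(50, 200.0)))
        assert m.sdrr == 0.0 and m.rmssd == 0.0 and m.sd1 == 0.0

    def test_alternating_series_closed_form(self):
        rr = np.tile([200.0, 220.0], 500)
        m = hrv_metrics(RrSeries(rr=rr))
        assert m.rmssd == pytest.approx(20.0, rel=1e-9)
        assert m.sd1 == pytest.approx(20.0 / np.sqrt(2.0), rel=1e-3)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rr = rng.uniform(150.0, 600.0, rng.integers(5, 200))
            m = hrv_metrics(RrSeries(rr=rr))
            sdrr, rmssd, sd1 = brute_force_metrics(list(rr))
            assert m.sdrr == pytest.approx(sdrr, rel=1e-9)
            assert m.rmssd == pytest.approx(rmssd, rel=1e-9)
            assert m.sd1 == pytest.approx(sd1, rel=1e-9)

    def test_sd1_identity_sd_of_differences(self):
        rng = np.random.default_rng(11)
        rr = rng.uniform(200.0, 500.0, 1000)
        m = hrv_metrics(RrSeries(rr=rr))
        assert m.sd1 == pytest.approx(np.std(np.diff(rr), ddof=1) / np.sqrt(2.0),
                                      abs=1e-9)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(3)
        rr = rng.uniform(200.0, 500.0, 500)
        m_f = hrv_metrics(RrSeries(rr=rr))
        m_r = hrv_metrics(RrSeries(rr=rr[::-1].copy()))
        assert m_f.sdrr == pytest.approx(m_r.sdrr, rel=1e-12)
        assert m_f.rmssd == pytest.approx(m_r.rmssd, rel=1e-12)
        assert m_f.sd1 == pytest.approx(m_r.sd1, rel=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            hrv_metrics(RrSeries(rr=np.array([200.0, 210.0])))

    def test_nonpositive_intervals_rejected(self):
        with pytest.raises(ValueError):
            RrSeries(rr=np.array([200.0, -5.0, 210.0]))


class TestOutlierClusters:
    def test_clean_series_no_clusters(self):
        rr = gen_rr(RrGenConfig(base_cl=300.0, jitter_sd=4.0, n_beats=500, seed=1))
        rep = detect_outlier_clusters(rr)
        assert not rep.has_clusters

    def test_short_coupled_cluster_detected(self):
        cfg = RrGenConfig(base_cl=400.0, jitter_sd=3.0, ectopic_prob=0.05,
                          ectopic_factor=0.6, n_beats=1000, seed=2)
        rr = gen_rr(cfg)
        rep = detect_outlier_clusters(rr)
        assert rep.short_indices.size > 0
        # flagged beats are predominantly true ectopics
        hits = (rr.labels[rep.short_indices] == "ectopic").mean()
        assert hits > 0.9

    def test_pause_cluster_detected(self):
        cfg = RrGenConfig(base_cl=400.0, jitter_sd=3.0, pause_prob=0.03,
                          pause_factor=2.0, n_beats=1000, seed=3)
        rr = gen_rr(cfg)
        rep = detect_outlier_clusters(rr)
        assert rep.pause_indices.size > 0
        hits = (rr.labels[rep.pause_indices] == "pause").mean()
        assert hits > 0.9

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_outlier_clusters(RrSeries(rr=np.full(10, 300.0)))


class TestRateResponse:
    def test_identical_series_zero(self):
        rr = RrSeries(rr=np.full(50, 400.0))
        assert rate_response(rr, rr) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        base = RrSeries(rr=np.full(50, 400.0))
        chall = RrSeries(rr=np.full(50, 250.0))
        assert rate_response(base, chall) == pytest.approx(60.0, rel=1e-12)

    def test_chronotropic_percentage_from_rates(self):
        # baseline 144.1 bpm, challenge 185 bpm -> +28.4%
        base = RrSeries(rr=np.full(60, 60000.0 / 144.1))
        chall = RrSeries(rr=np.full(60, 60000.0 / 185.0))
        assert rate_response(base, chall) == pytest.approx(28.4, abs=0.05)


class TestCorrectedRecoveryTime:
    def test_zero_crt_when_recovery_equals_cl(self):
        res = corrected_recovery_time([10400.0], [10000.0], 400.0)
        assert res.crt == pytest.approx(0.0)

    def test_crt_arithmetic(self):
        # recovery 524.6 ms at spontaneous CL 400 -> cRT 124.6 ms
        res = corrected_recovery_time([10524.6], [10000.0], 400.0)
        assert res.crt == pytest.approx(124.6, rel=1e-12)

    def test_offset_invariance(self):
        a = corrected_recovery_time([1000.0, 1500.0], [600.0], 400.0)
        b = corrected_recovery_time([101000.0, 101500.0], [100600.0], 400.0)
        assert a.crt == pytest.approx(b.crt)

    def test_multiple_trains_averaged(self):
        res = corrected_recovery_time(
            [1500.0, 11600.0, 21700.0], [1000.0, 11000.0, 21000.0], 400.0)
        assert res.crts == pytest.approx([100.0, 200.0, 300.0])
        assert res.crt == pytest.approx(200.0)

    def test_suppression_failure_flagged(self):
        res = corrected_recovery_time(
            [1500.0], [1000.0, 50000.0], 400.0, timeout_factor=10.0)
        assert res.suppression_failures == 1
        assert res.crt == pytest.approx(100.0)


class TestRrFromSignal:
    def test_exact_spacing_recovered(self):
        rr_true = RrSeries(rr=np.full(40, 250.0))
        sig = gen_signal(rr_true, 10000.0, SignalTemplateConfig(snr_db=None))
        rr = rr_from_signal(sig, 10000.0)
        assert len(rr) == 40
        assert np.allclose(rr.rr, 250.0, atol=0.2)

    def test_double_interval_outlier_recovered(self):
        intervals = np.full(40, 250.0)
        intervals[20] = 500.0
        sig = gen_signal(RrSeries(rr=intervals), 10000.0,
                         SignalTemplateConfig(snr_db=None))
        rr = rr_from_signal(sig, 10000.0)
        assert np.sum(rr.rr > 400.0) == 1
        assert rr.rr.max() == pytest.approx(500.0, abs=0.5)

    def test_polarity_invariance(self):
        rr_true = gen_rr(RrGenConfig(base_cl=300.0, jitter_sd=10.0,
                                     n_beats=50, seed=5))
        sig = gen_signal(rr_true, 10000.0, SignalTemplateConfig(snr_db=30.0))
        a = rr_from_signal(sig, 10000.0)
        b = rr_from_signal(-sig, 10000.0)
        assert len(a) == len(b)
        assert np.allclose(a.rr, b.rr, atol=0.3)

    def test_no_beats_flagged_as_empty(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0.0, 1e-6, 5000)
        rr = rr_from_signal(sig, 10000.0)
        assert len(rr) == 0
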