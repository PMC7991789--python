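"""Temporal cleaning: FD/DVARS, scrubbing rule, regression, band-pass."""

import numpy as np
import pytest

import fconn
from fconn.cohort import MotionTrace, RoiTimeSeriesSet
from fconn.preprocess import (
    bandpass,
    compute_dvars,
    compute_fd,
    friston24,
    nuisance_regress,
    scrub,
)


def _ts(data, tr=2.0, mask=None, **kw):
    data = np.asarray(data, dtype=float)
    mask = np.ones(len(data), bool) if mask is None else mask
    return RoiTimeSeriesSet(subject_id="s", data=data, tr_seconds=tr, valid_mask=mask, **kw)


def _trace(params, dvars=None):
    params = np.asarray(params, dtype=float)
    fd = compute_fd(params)
    dv = np.zeros(len(params)) if dvars is None else np.asarray(dvars, float)
    return MotionTrace(params=params, fd=fd, dvars=dv)


class TestFd:
    def test_constant_params_zero(self):
        assert compute_fd(np.ones((10, 6))).max() == 0.0

    def test_translation_step_sums_absolute_differences(self):
        p = np.zeros((3, 6))
        p[1, :3] = 0.1  # +0.1 mm on each translation at frame 1
        fd = compute_fd(p)
        np.testing.assert_allclose(fd, [0.0, 0.3, 0.3])

    def test_rotation_projected_on_50mm_sphere(self):
        p = np.zeros((2, 6))
        p[1, 3] = 0.01  # 0.01 rad on one axis
        np.testing.assert_allclose(compute_fd(p), [0.0, 0.5])

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6 motion parameters"):
            compute_fd(np.zeros((10, 5)))


class TestDvars:
    def test_constant_signal_zero(self):
        np.testing.assert_allclose(compute_dvars(np.full((10, 4), 100.0)), 0.0)

    def test_known_step_change(self):
        # one uniform +1 step on baseline 100 -> rms diff 1 -> 1 % of mean
        data = np.full((4, 5), 100.0)
        data[2:] += 1.0
        dv = compute_dvars(data)
        np.testing.assert_allclose(dv, [0.0, 0.0, 100 / 100.5, 0.0], atol=1e-9)


class TestScrub:
    def test_clean_series_untouched(self):
        ts = _ts(np.random.default_rng(0).normal(size=(20, 3)))
        trace = _trace(np.zeros((20, 6)))
        out, rep = scrub(ts, trace)
        assert rep.fraction == 0.0 and out.valid_mask.all()

    def test_fraction_counts_frames_exceeding_both(self):
        n = 195
        ts = _ts(np.zeros((n, 2)) + 1.0)
        params = np.zeros((n, 6))
        dvars = np.zeros(n)
        for f in (10, 50, 90):
            params[f, 0] = 2.0  # spike -> FD > 0.5 at f and f+1
            dvars[f] = 1.0  # but DVARS only at f: AND keeps f+1
        trace = _trace(params, dvars)
        out, rep = scrub(ts, trace)
        assert rep.n_scrubbed == 3
        assert rep.fraction == pytest.approx(3 / 195, abs=1e-12)
        assert not out.valid_mask[[10, 50, 90]].any()

    def test_and_rule_retains_fd_only_exceedance(self):
        ts = _ts(np.ones((5, 2)))
        params = np.zeros((5, 6))
        params[2, 0] = 0.6
        trace = _trace(params, dvars=[0, 0, 0.1, 0, 0])
        out, rep = scrub(ts, trace)
        assert out.valid_mask.all() and rep.n_scrubbed == 0
        out_or, rep_or = scrub(ts, trace, rule="or")
        assert rep_or.n_scrubbed > 0 and not out_or.valid_mask[2]

    def test_excessive_scrubbing_flagged(self, caplog):
        n = 100
        ts = _ts(np.ones((n, 2)))
        params = np.zeros((n, 6))
        params[10:21, 0] = np.arange(11) * 2.0
        dvars = np.zeros(n)
        dvars[10:22] = 1.0
        with caplog.at_level("WARNING", logger="fconn.preprocess"):
            _, rep = scrub(ts, _trace(params, dvars))
        assert rep.flagged
        assert any("scrubbed" in m for m in caplog.messages)


class TestNuisanceRegression:
    def test_confound_equal_node_removed(self, rng):
        n = 60
        wm = rng.normal(size=n)
        data = np.column_stack([wm, rng.normal(size=n)])
        ts = _ts(data)
        trace = _trace(np.zeros((n, 6)))
        out = nuisance_regress(ts, trace, wm_signal=wm)
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_orthogonal_signal_unchanged(self, rng):
        n = 100
        base = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        noise = rng.normal(size=n)
        sig = noise - base @ np.linalg.lstsq(base, noise, rcond=None)[0]
        motion = np.zeros((n, 6))
        out = nuisance_regress(_ts(sig[:, None]), _trace(motion))
        np.testing.assert_allclose(out.data[:, 0], sig, atol=1e-8)

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        n = 120
        params = rng.normal(size=(n, 6)) * 0.01
        wm, csf = rng.normal(size=n), rng.normal(size=n)
        data = rng.normal(size=(n, 7))
        out = nuisance_regress(_ts(data), _trace(params), wm, csf)
        design = np.column_stack(
            [np.ones(n), np.linspace(-1, 1, n), friston24(params), wm, csf]
        )
        prods = np.abs(design.T @ out.data)
        assert prods.max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self, rng, caplog):
        n = 50
        params = np.zeros((n, 6))
        params[:, 0] = np.linspace(-1, 1, n)  # duplicates the trend regressor
        with caplog.at_level("WARNING", logger="fconn.preprocess"):
            nuisance_regress(_ts(rng.normal(size=(n, 3))), _trace(params))
        assert any("rank-deficient" in m for m in caplog.messages)


class TestBandpass:
    def test_out_of_band_attenuated(self):
        n, tr = 200, 2.0
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(_ts(sig[:, None], tr=tr))
        assert (out.data**2).sum() < 0.01 * (sig**2).sum()

    def test_in_band_passthrough(self):
        n, tr = 200, 2.0
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(_ts(sig[:, None], tr=tr))
        assert (out.data**2).sum() > 0.99 * (sig**2).sum()

    def test_zero_signal_stays_zero(self):
        out = bandpass(_ts(np.zeros((100, 3))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_empty_band_raises(self):
        with pytest.raises(ValueError, match="empty pass band"):
            bandpass(_ts(np.zeros((100, 2))), low=0.011, high=0.012)

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_ts(np.zeros((100, 2)), tr=2.0), high=0.3)

    def test_invalid_frames_interpolated_and_recensored(self, rng):
        n = 150
        mask = np.ones(n, bool)
        mask[40:43] = False
        data = rng.normal(size=(n, 2))
        data[40:43] = 1e6  # garbage in censored frames must not leak
        out = bandpass(_ts(data, mask=mask))
        assert np.isfinite(out.data).all()
        assert np.abs(out.data[mask]).max() < 100
        assert not out.valid_mask[40:43].any()

    def test_filter_is_idempotent(self, rng):
        ts = _ts(rng.normal(size=(180, 4)))
        once = bandpass(ts)
        twice = bandpass(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


def test_clean_pipeline_produces_qc(small_cohort):
    _, ts_sets, motions = small_cohort
    cleaned, qc = fconn.clean_pipeline(ts_sets[0], motions[0])
    assert cleaned.data.shape == ts_sets[0].data.shape
    assert qc.max_fd >= qc.mean_fd >= 0
    assert 0 <= qc.scrub_fraction <= 1
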