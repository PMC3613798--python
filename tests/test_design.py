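"""Design construction, HRF properties and the DCT high-pass filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma

from dotgrouping.design import (
    DesignError,
    build_design,
    dct_basis,
    highpass,
    standard_contrasts,
)
from dotgrouping.glm import contrast_t, fit_glm
from dotgrouping.hrf import HRFSpec, hrf_kernel


def _nuisance(n):
    rng = np.random.default_rng(0)
    cols = {f"motion_{i}": rng.normal(size=n) for i in range(6)}
    cols["keypress"] = (np.arange(n) % 7 == 0).astype(float)
    return pd.DataFrame(cols)


class TestHRF:
    def test_kernel_positive_unit_sum_with_undershoot(self):
        k = hrf_kernel(HRFSpec(), dt=0.1)
        assert np.isclose(k.sum(), 1.0)
        assert k.max() > 0
        assert k.min() < 0  # the undershoot

    def test_peak_near_five_seconds(self):
        dt = 0.05
        k = hrf_kernel(HRFSpec(), dt=dt)
        assert 4.0 <= np.argmax(k) * dt <= 6.0


class TestBuildDesign:
    def test_parametric_variant_column_count(self, all_type_events):
        dm = build_design(
            all_type_events, n_volumes=30, tr=3.264, nuisance=_nuisance(30)
        )
        # 4 conditions + 4 derivatives + 2 modulators + 2 modulator
        # derivatives + 7 nuisance + intercept
        assert dm.n_regressors == 20
        assert dm.roles.count("condition") == 4
        assert dm.roles.count("modulator") == 2
        assert dm.roles.count("nuisance") == 7

    def test_six_condition_variant_columns(self, all_type_events):
        dm = build_design(
            all_type_events, n_volumes=30, tr=3.264, variant="six_condition"
        )
        assert dm.roles.count("condition") == 6
        assert dm.roles.count("derivative") == 6

    def test_modulator_matches_independent_convolution_oracle(self, all_type_events):
        tr, n_vol, over = 3.264, 30, 16
        dm = build_design(all_type_events, n_volumes=n_vol, tr=tr)
        # oracle: centred n_groups boxcar convolved independently
        dt = tr / over
        t_fine = np.arange(0, 32.0, dt)
        kern = gamma.pdf(t_fine, 6.0, scale=1.0) - gamma.pdf(t_fine, 16.0, scale=1.0) / 6.0
        series = np.zeros(n_vol * over)
        mc = all_type_events[all_type_events["trial_type"] == "moving_colour"]
        centred = mc["n_groups"].to_numpy(float) - mc["n_groups"].mean()
        for onset, value in zip(mc["onset"], centred):
            lo = int(round(onset / dt))
            series[lo : lo + int(round(5.0 / dt))] += value
        oracle = np.convolve(series, kern)[: n_vol * over][:: over]
        column = dm.column("moving_colour_x_n_groups")
        r = np.corrcoef(oracle, column)[0, 1]
        assert r > 0.99

    def test_single_event_column_peaks_near_six_seconds(self):
        events = pd.DataFrame(
            [{"onset": 0.0, "duration": 5.0, "trial_type": "moving_colour", "n_groups": 0}]
        )
        dm = build_design(events, n_volumes=30, tr=1.0, add_derivatives=False)
        peak_s = float(np.argmax(dm.column("moving_colour")))
        assert 5.0 <= peak_s <= 8.0  # 5-s boxcar shifts the kernel peak later

    def test_collinear_columns_are_named(self, all_type_events):
        nuis = _nuisance(30)
        nuis["motion_dup"] = nuis["motion_0"]
        with pytest.raises(DesignError, match="collinear"):
            build_design(all_type_events, n_volumes=30, tr=3.264, nuisance=nuis)

    def test_events_outside_scan_rejected(self, all_type_events):
        with pytest.raises(DesignError, match="outside"):
            build_design(all_type_events, n_volumes=5, tr=3.264)


class TestHighpass:
    def _sine_design(self, n, tr):
        events = pd.DataFrame(
            [{"onset": 0.0, "duration": 5.0, "trial_type": "moving_colour", "n_groups": 0}]
        )
        return build_design(events, n_volumes=n, tr=tr, add_derivatives=False)

    def test_slow_drift_removed_fast_signal_kept(self):
        n, tr = 140, 3.264
        dm = self._sine_design(n, tr)
        t = np.arange(n) * tr
        slow = np.sin(2 * np.pi * t / 240.0 + 0.3)[:, None]
        fast = np.sin(2 * np.pi * t / 40.0 + 0.3)[:, None]
        _, slow_f = highpass(dm, slow, 120.0)
        _, fast_f = highpass(dm, fast, 120.0)
        assert np.sum(slow_f**2) / np.sum(slow**2) < 0.01
        assert np.sum(fast_f**2) / np.sum(fast**2) > 0.95

    def test_filter_is_idempotent(self, rng):
        n, tr = 140, 3.264
        dm = self._sine_design(n, tr)
        data = rng.normal(size=(n, 4))
        dm1, d1 = highpass(dm, data, 120.0)
        dm2, d2 = highpass(dm1, d1, 120.0)
        np.testing.assert_allclose(d2, d1, atol=1e-12)
        np.testing.assert_allclose(dm2.matrix, dm1.matrix, atol=1e-12)

    def test_short_scan_is_a_noop_with_warning(self, rng):
        dm = self._sine_design(10, 3.264)
        data = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning, match="no-op"):
            _, out = highpass(dm, data, 120.0)
        np.testing.assert_array_equal(out, data)

    def test_filtering_equals_dct_confound_columns(self, all_type_events, rng):
        """Projecting out the DCT set must match including it as confounds."""
        n, tr = 60, 3.264
        dm = build_design(all_type_events, n_volumes=n, tr=tr)
        data = rng.normal(size=(n, 25)) + np.linspace(0, 3, n)[:, None]

        dm_f, data_f = highpass(dm, data, 120.0)
        t_filtered = contrast_t(fit_glm(dm_f, data_f), dm_f.contrast_vector({"moving_colour": 1.0})).t

        basis = dct_basis(n, tr, 120.0)
        from dotgrouping.design import DesignMatrix

        aug = DesignMatrix(
            matrix=np.column_stack([dm.matrix, basis]),
            names=dm.names + [f"dct_{k}" for k in range(basis.shape[1])],
            roles=dm.roles + ["nuisance"] * basis.shape[1],
            tr=tr,
        )
        t_confound = contrast_t(fit_glm(aug, data), aug.contrast_vector({"moving_colour": 1.0})).t
        np.testing.assert_allclose(t_filtered, t_confound, atol=1e-6)


def test_standard_contrasts_cover_both_variants(all_type_events):
    dm6 = build_design(all_type_events, n_volumes=30, tr=3.264, variant="six_condition")
    c6 = standard_contrasts(dm6)
    assert {"colour_grouping_gt_none", "motion_grouping_gt_none",
            "none_gt_colour_grouping", "colour_gt_greyscale_static"} <= set(c6)
    dm4 = build_design(all_type_events, n_volumes=30, tr=3.264)
    c4 = standard_contrasts(dm4)
    assert {"colour_slope", "motion_slope"} <= set(c4)
    np.testing.assert_array_equal(
        c6["colour_grouping_gt_none"], -c6["none_gt_colour_grouping"]
    )
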