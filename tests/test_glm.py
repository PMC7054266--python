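"""First-level GLM: HRF, design construction, OLS, level combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sessm.glm import (EventRegressor, build_design, combine_levels,
                       dct_drift, double_gamma_hrf, dv_event_onsets,
                       extract_clusters, fit_glm, fixed_effects_combine,
                       log_zscore_rt, one_sample_group)


class TestHRF:
    def test_peaks_near_five_seconds(self):
        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.15)
        assert h.max() == pytest.approx(1.0)

    def test_zero_at_onset(self):
        h = double_gamma_hrf(np.arange(0, 32, 0.1))
        assert h[0] == 0.0

    def test_exactly_one_sign_change(self):
        h = double_gamma_hrf(np.arange(0.1, 32, 0.1))
        signs = np.sign(h[np.abs(h) > 1e-12])
        assert (np.diff(signs) != 0).sum() == 1  # lobe then undershoot


class TestBuildDesign:
    def test_linearity_in_amplitudes(self):
        on = np.array([10.0, 30.0, 55.0])
        a = np.array([1.0, 0.5, 2.0])
        b = np.array([0.3, 1.5, -0.5])
        mk = lambda amp: build_design(
            [EventRegressor("e", on, 1.0, amp)], 60, tr=2.0
        ).frame["e"].to_numpy()
        assert np.max(np.abs(mk(a + b) - (mk(a) + mk(b)))) < 1e-10
        assert np.max(np.abs(mk(2 * a) - 2 * mk(a))) < 1e-10

    def test_rt_amplitudes_are_zscored(self):
        rts = np.random.default_rng(0).uniform(0.3, 1.2, 50)
        amps = log_zscore_rt(rts)
        assert amps.mean() == pytest.approx(0, abs=1e-12)
        assert amps.std() == pytest.approx(1, abs=1e-12)

    def test_dv_event_timing(self):
        # onset 10 s, RT 0.5 s, window center -25 ms, 100 ms duration
        # -> event centered at 10.475 s, so it starts at 10.425 s
        onsets, dur = dv_event_onsets([10.0], [0.5], -0.025, duration=0.1)
        assert onsets[0] == pytest.approx(10.425)
        assert dur == 0.1

    def test_event_beyond_scan_end_raises(self):
        with pytest.raises(ValueError, match="outside the scan"):
            build_design([EventRegressor("e", [500.0], 1.0)], 100, tr=2.0)

    def test_drift_columns_added(self):
        d = build_design([EventRegressor("e", [10.0], 1.0)], 151, tr=2.0,
                         highpass=100.0)
        drift_cols = [c for c in d.columns if c.startswith("drift_")]
        # 302 s of data at 100 s cutoff -> 6 cosine terms
        assert len(drift_cols) == 6
        assert d.task_columns == ["e"]


class TestFitGLM:
    def test_exact_recovery_without_noise(self):
        on = np.arange(5, 290, 20.0)
        d = build_design([EventRegressor("a", on, 1.0),
                          EventRegressor("b", on + 7, 1.0)], 151, tr=2.0)
        beta_true = np.array([2.0, -1.0, 5.0])
        y = d.values @ beta_true
        res = fit_glm(y, d, {"a": [1, 0], "sum": [1, 1]})
        assert np.allclose(res.betas.ravel(), beta_true, atol=1e-8)
        assert res.contrast("sum")["estimate"][0] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        on = np.arange(5, 290, 15.0)
        d = build_design([EventRegressor("e", on, 1.0)], 151, tr=2.0)
        y = rng.standard_normal((151, 1000))
        res = fit_glm(y, d, {"e": [1.0]})
        t = res.contrast("e")["t"]
        pvals = stats.t.sf(t, res.dof)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sum_contrast_equals_sum_of_betas(self):
        rng = np.random.default_rng(2)
        on = np.arange(5, 280, 20.0)
        d = build_design([EventRegressor("stim", on, 1.0),
                          EventRegressor("dv0", on + 5, 1.0),
                          EventRegressor("dv1", on + 9, 1.0)], 151, tr=2.0)
        y = rng.standard_normal(151)
        res = fit_glm(y, d, {"dv_sum": [0, 1, 1]})
        est = res.contrast("dv_sum")["estimate"][0]
        assert est == pytest.approx(res.beta("dv0")[0] + res.beta("dv1")[0])

    def test_rank_deficient_design_names_columns(self):
        on = np.arange(5, 280, 20.0)
        d = build_design([EventRegressor("a", on, 1.0),
                          EventRegressor("b", on, 1.0)], 151, tr=2.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.zeros(151), d)


class TestCombineLevels:
    def test_two_identical_sessions_pass_through(self):
        est = np.array([[1.0, 2.0], [1.0, 2.0]])
        var = np.ones_like(est)
        comb, v = fixed_effects_combine(est, var)
        assert np.allclose(comb, [1.0, 2.0])
        assert np.allclose(v, 0.5)

    def test_single_session_is_identity(self):
        comb, v = fixed_effects_combine([[3.0]], [[2.0]])
        assert comb[0] == 3.0 and v[0] == 2.0

    def test_planted_activation_recovered_as_cluster(self):
        rng = np.random.default_rng(8)
        maps = rng.standard_normal((21, 10, 10, 10))
        maps[:, 4:6, 4:6, 4:6] += 2.0  # strong planted group effect
        group = one_sample_group(maps)
        clusters = extract_clusters(group["z"], threshold=2.5)
        assert clusters
        planted = {(i, j, k) for i in (4, 5) for j in (4, 5) for k in (4, 5)}
        assert planted <= set(clusters[0]["voxels"])

    def test_no_suprathreshold_voxels_gives_empty_list(self):
        assert extract_clusters(np.zeros((5, 5, 5)), threshold=2.5) == []

    def test_nested_session_subject_combination(self):
        rng = np.random.default_rng(9)
        per_subject = [rng.standard_normal((2, 50)) + 1.0 for _ in range(12)]
        out = combine_levels(per_subject)
        assert out["subject_maps"].shape == (12, 50)
        assert out["z"].shape == (50,)
        assert out["dof"] == 11
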