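import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vocalchimera.design import build_expt2_sequence
from vocalchimera.glm import (DesignMatrix, RoiGlm, build_design_matrix,
                              canonical_hrf, gg_epsilon, group_contrast,
                              rm_anova_2x2, rm_anova_gg, simulate_roi_bold)
from vocalchimera.recovery import (FACTORIAL_CELLS, VOICE_CELL, expt2_design,
                                   mock_factorial_entries, recover_voice_effect)


@pytest.fixture(scope="module")
def design():
    return expt2_design(seed=0)


class TestCanonicalHrf:
    def test_peak_time_in_physiological_range(self):
        h = canonical_hrf(0.1)
        assert 4.0 <= np.argmax(h) * 0.1 <= 7.0

    def test_starts_at_zero_and_undershoots(self):
        h = canonical_hrf(0.1)
        assert abs(h[0]) < 1e-6
        assert h[np.argmax(h):].min() < 0.0

    def test_matches_spm_canonical_shape(self):
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        mine = canonical_hrf(0.1)
        ref = spm_hrf(0.1, oversampling=1)
        n = min(mine.size, ref.size)
        assert np.corrcoef(mine[:n], ref[:n])[0, 1] > 0.999


@pytest.fixture(scope="module")
def modulated_design():
    seq = build_expt2_sequence(mock_factorial_entries(), seed=1)
    rng = np.random.default_rng(0)
    ids = sorted({t.stimulus_id for t in seq.trials})
    table = pd.DataFrame(dict(
        id=ids,
        f0_hz=rng.normal(300, 50, len(ids)),
        hnr_db=rng.normal(24, 4, len(ids)),
        dom_scale_cpo=rng.normal(1.3, 0.2, len(ids)),
        dom_rate_hz=rng.normal(8, 1, len(ids)),
        centroid_hz=rng.normal(1500, 200, len(ids)),
    ))
    return build_design_matrix(seq, modulators=table)


class TestBuildDesignMatrix:
    def test_column_structure(self, modulated_design):
        d = modulated_design
        assert len(d.condition_names) == 4
        assert len(d.modulator_names) == 5
        assert d.frame.shape[1] == 4 + 5 + 1

    def test_modulators_orthogonal_to_earlier_columns(self, modulated_design):
        d = modulated_design
        order = ["intercept"] + d.condition_names + d.modulator_names
        X = d.frame[order].to_numpy()
        scale = np.linalg.norm(X, axis=0)
        for j, name in enumerate(order):
            if not name.startswith("mod_"):
                continue
            for i in range(j):
                dot = X[:, i] @ X[:, j] / (scale[i] * scale[j])
                assert abs(dot) < 1e-8, (name, order[i])

    def test_condition_columns_silent_before_first_event(self, design):
        first_scan_cols = design.frame[design.condition_names].iloc[0]
        assert (first_scan_cols.abs() < 1e-12).all()

    def test_missing_modulator_rows_raise(self):
        seq = build_expt2_sequence(mock_factorial_entries(), seed=1)
        table = pd.DataFrame(dict(id=["nope"], f0_hz=[1.0], hnr_db=[1.0],
                                  dom_scale_cpo=[1.0], dom_rate_hz=[1.0],
                                  centroid_hz=[1.0]))
        with pytest.raises(KeyError):
            build_design_matrix(seq, modulators=table)


class TestSimulateRoiBold:
    def test_noiseless_equals_linear_prediction(self, design):
        truth = {c: 1.0 + 0.1 * i for i, c in enumerate(FACTORIAL_CELLS)}
        y = simulate_roi_bold(design, truth, noise_sd=0.0)
        X = design.frame[list(truth)].to_numpy()
        np.testing.assert_allclose(y.values, X @ np.array(list(truth.values())),
                                   atol=1e-12)

    def test_beta_scaling_is_linear(self, design):
        y1 = simulate_roi_bold(design, {VOICE_CELL: 1.0}, noise_sd=0.0)
        y2 = simulate_roi_bold(design, {VOICE_CELL: 2.0}, noise_sd=0.0)
        np.testing.assert_allclose(y2.values, 2.0 * y1.values, atol=1e-12)

    def test_ar1_autocorrelation_matches_rho(self):
        frame = pd.DataFrame({"intercept": np.zeros(40000)})
        d = DesignMatrix(frame=frame, tr_s=2.0, condition_names=[])
        y = simulate_roi_bold(d, {}, noise_sd=1.0, ar1_rho=0.4, seed=0).values
        rho_hat = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert rho_hat == pytest.approx(0.4, abs=0.02)
        assert y.std() == pytest.approx(1.0, abs=0.03)

    def test_unknown_beta_name_raises(self, design):
        with pytest.raises(KeyError):
            simulate_roi_bold(design, {"not-a-column": 1.0})


class TestRoiGlmFit:
    def test_noiseless_recovery_exact(self, design):
        truth = {c: 0.5 + 0.25 * i for i, c in enumerate(FACTORIAL_CELLS)}
        res = RoiGlm.from_simulation(design, truth, noise_sd=0.0).fit()
        for c in FACTORIAL_CELLS:
            assert res.params[c] == pytest.approx(truth[c], abs=1e-8)

    def test_estimates_unbiased_over_seeds(self, design):
        truth = {c: 1.0 for c in FACTORIAL_CELLS}
        truth[VOICE_CELL] = 1.5
        pinv = np.linalg.pinv(design.matrix)
        cols = list(design.frame.columns)
        v = cols.index(VOICE_CELL)
        errs = []
        for seed in range(200):
            y = simulate_roi_bold(design, truth, noise_sd=1.0, ar1_rho=0.2,
                                  seed=seed)
            errs.append((pinv @ y.values)[v] - 1.5)
        assert abs(np.mean(errs)) < 0.05 * 1.5

    def test_residual_variance_tracks_white_noise(self, design):
        scales = []
        for seed in range(20):
            res = RoiGlm.from_simulation(design, {VOICE_CELL: 1.0}, noise_sd=2.0,
                                         ar1_rho=0.0, seed=seed).fit()
            scales.append(res.scale)
        assert np.mean(scales) == pytest.approx(4.0, rel=0.05)

    def test_summary_renders(self, design):
        res = RoiGlm.from_simulation(design, {VOICE_CELL: 1.0}, seed=0).fit()
        text = res.summary()
        assert "df_resid" in text and VOICE_CELL in text


def paired_t_oracle(a, b):
    """Textbook paired-t formula."""
    d = np.asarray(a) - np.asarray(b)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * stats.t.sf(abs(t), n - 1)


class TestGroupContrast:
    def test_equal_conditions_give_t_zero(self):
        a = np.arange(5.0)
        res = group_contrast(a, a.copy())
        assert res.t == 0.0 and res.p == 1.0 and res.df == 4

    def test_constant_difference_flagged_degenerate(self):
        res = group_contrast(np.arange(5.0) + 1.0, np.arange(5.0))
        assert res.degenerate and np.isinf(res.t)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=5)
        res = group_contrast(a, b)
        t_ref, p_ref = paired_t_oracle(a, b)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)

    def test_mean_of_multiple_conditions(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=6)
        b = rng.normal(size=(6, 3))
        res = group_contrast(a, b)
        t_ref, _ = paired_t_oracle(a, b.mean(axis=1))
        assert res.t == pytest.approx(t_ref, abs=1e-12)


class TestRmAnova2x2:
    def test_all_cells_equal_give_zero_f(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 4))
        out = rm_anova_2x2(data)
        assert all(r.F == 0.0 and r.p == 1.0 for r in out.values())

    def test_dfs_are_one_and_n_minus_one(self):
        rng = np.random.default_rng(0)
        out = rm_anova_2x2(rng.normal(size=(8, 4)))
        assert all(r.df1 == 1 and r.df2 == 7 for r in out.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        import pingouin as pg

        rng = np.random.default_rng(seed)
        data = rng.normal(size=(5, 4))
        mine = rm_anova_2x2(data, factor_names=("t", "s"))
        long = pd.DataFrame([
            dict(subject=i, t=c[0], s=c[1], y=data[i, j])
            for i in range(5)
            for j, c in enumerate([("V", "V"), ("V", "I"), ("I", "V"), ("I", "I")])
        ])
        ref = pg.rm_anova(data=long, dv="y", within=["t", "s"], subject="subject",
                          detailed=True).set_index("Source")
        assert mine["t"].F == pytest.approx(ref.loc["t", "F"], rel=1e-8)
        assert mine["s"].F == pytest.approx(ref.loc["s", "F"], rel=1e-8)
        assert mine["t:s"].F == pytest.approx(ref.loc["t * s", "F"], rel=1e-8)

    def test_pure_spectrum_effect_detected(self):
        rng = np.random.default_rng(42)
        n = 22
        base = rng.normal(1.0, 0.3, size=(n, 1))
        data = np.repeat(base, 4, axis=1) + rng.normal(0, 0.1, size=(n, 4))
        data[:, [0, 2]] += 0.3      # S=Voice columns under default cell order
        out = rm_anova_2x2(data, factor_names=("t", "s"))
        assert out["s"].p < 0.01
        assert out["t"].p > 0.01 and out["t:s"].p > 0.01


class TestRmAnovaGg:
    def test_epsilon_bounds_hold(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            eps = gg_epsilon(rng.normal(size=(6, 4)))
            assert 1.0 / 3.0 <= eps <= 1.0

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(2)
        subj = rng.normal(0, 1, size=(200, 1))
        data = subj + rng.normal(0, 1, size=(200, 4))
        assert gg_epsilon(data) > 0.9

    def test_uncorrected_df1_is_k_minus_one(self):
        rng = np.random.default_rng(3)
        res = rm_anova_gg(rng.normal(size=(10, 4)))
        assert res.df1 == pytest.approx(res.gg_epsilon * 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_f_and_epsilon(self, seed):
        import pingouin as pg

        rng = np.random.default_rng(seed)
        data = rng.normal(size=(5, 4))
        mine = rm_anova_gg(data)
        long = pd.DataFrame([dict(subject=i, cond=j, y=data[i, j])
                             for i in range(5) for j in range(4)])
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          correction=True)
        assert mine.F == pytest.approx(ref["F"].iloc[0], rel=1e-8)
        assert mine.gg_epsilon == pytest.approx(ref["eps"].iloc[0], rel=1e-6)
        assert mine.p == pytest.approx(ref["p_GG_corr"].iloc[0], rel=1e-6)


class TestRecoverVoiceEffect:
    def test_zero_noise_recovers_betas_exactly(self):
        rep = recover_voice_effect(n_subjects=4, noise_sd=0.0, between_sd=0.0,
                                   effect_d=0.8, seed=0, shared_design=True)
        # with both noise sources off, all injected amplitudes are 1.0
        np.testing.assert_allclose(rep.betas_null, 1.0, atol=1e-8)
        np.testing.assert_allclose(rep.betas_selective, 1.0, atol=1e-8)
        assert rep.recovered_effect_mean == pytest.approx(0.0, abs=1e-8)

    def test_selective_roi_detected_null_roi_not(self):
        rep = recover_voice_effect(n_subjects=22, seed=7)
        assert rep.selective_contrast.p < 0.05
        assert rep.recovered_effect_mean == pytest.approx(
            rep.injected_effect_mean, abs=0.15)
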