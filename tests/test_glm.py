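"""Parametric GLM, condition-cell extraction and within-subject ANOVA."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import audconn as ac
from audconn.dcm import RoiTimeSeries
from audconn.glm import GLMError, GLMFit, percent_signal_change, posthoc_lsd
from audconn.invert import dct_highpass_basis

NODES = ("L_medial_AC", "L_lateral_AC", "L_PT", "R_medial_AC", "R_lateral_AC")


@pytest.fixture(scope="module")
def design():
    return ac.generate_design(21, n_runs=5)


@pytest.fixture(scope="module")
def X(design):
    return ac.build_design_matrix(design)


def make_ts(values, tr=2.0, runs=(220,) * 5):
    return RoiTimeSeries(values, NODES, tr, runs)


class TestDesignMatrix:
    def test_four_run_baseline_columns(self, X):
        base = [n for n in X.names if n.startswith("run_baseline")]
        assert base == [f"run_baseline_{r}" for r in range(2, 6)]
        for r, name in enumerate(base, start=2):
            col = X.column(name)
            assert col.sum() == 220
            assert np.all(np.flatnonzero(col) // 220 == r - 1)

    def test_column_count_is_nine_plus_highpass(self, X):
        n_dct = sum(n.startswith("dct_") for n in X.names)
        assert X.X.shape[1] == 9 + n_dct
        # 256-s cutoff on 2200 s of data: K = floor(2*2200/256 + 1)
        assert n_dct == int(np.floor(2 * 2200 / 256 + 1))

    def test_convolved_columns_zero_before_first_stimulus(self, design, X):
        first = design.trials.onset.min()
        v_first = int(first // design.tr_s)
        for name in ("phonetic", "poa", "vot", "inter", "target"):
            assert np.all(X.column(name)[:v_first] == 0)

    def test_modulators_orthogonal_to_phonetic_presampling(self, design):
        u = ac.build_input_functions(design)
        for sig in (u.u_poa, u.u_vot, u.u_inter):
            assert abs(np.dot(u.u_phonetic, sig)) < 1e-8

    def test_empty_design_rejected(self, design):
        empty = ac.ExperimentalDesign(design.trials.iloc[:0], design.params)
        with pytest.raises(GLMError, match="empty"):
            ac.build_design_matrix(empty)
        with pytest.raises(GLMError, match="cutoff"):
            ac.build_design_matrix(design, highpass_s=3.0)


class TestFitGLM:
    def test_noiseless_recovery_exact(self, X):
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(X.X.shape[1], 5))
        fit = ac.fit_glm(make_ts(X.X @ beta), X)
        assert np.allclose(fit.betas.to_numpy(), beta, atol=1e-10)

    def test_white_noise_unbiased_monte_carlo(self, X):
        # 1000 replicates at once: one OLS on a (volumes x 1000) stack
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((X.n_volumes, 1000))
        b, *_ = np.linalg.lstsq(X.X, Y, rcond=None)
        i = X.names.index("phonetic")
        se = b[i].std(ddof=1) / np.sqrt(1000)
        assert abs(b[i].mean()) < 3 * se

    def test_highpass_absorbs_slow_drift(self, X, design):
        # a ~293-s cosine lying in the span of the DCT basis (mode 15)
        rng = np.random.default_rng(2)
        beta = rng.normal(size=(X.X.shape[1], 5))
        base = X.X @ beta
        n = X.n_volumes
        drift = 0.8 * np.cos(np.pi * 15 * (np.arange(n) + 0.5) / n)[:, None]
        fit0 = ac.fit_glm(make_ts(base), X)
        fit1 = ac.fit_glm(make_ts(base + drift), X)
        b0 = fit0.beta("phonetic").to_numpy()
        b1 = fit1.beta("phonetic").to_numpy()
        assert np.all(np.abs(b1 - b0) < 0.01 * np.abs(b0))

    def test_dct_basis_removes_slow_cosines(self):
        n, tr = 1100, 2.0
        B = dct_highpass_basis(n, tr, 256.0)
        # a basis-aligned slow cosine (mode 15, period ~293 s) is removed
        # exactly; an off-grid 300-s cosine is strongly attenuated but
        # leaves spectral leakage (documented behaviour of a DCT filter)
        aligned = np.cos(np.pi * 15 * (np.arange(n) + 0.5) / n)
        resid = aligned - B @ np.linalg.lstsq(B, aligned, rcond=None)[0]
        assert np.abs(resid).max() < 1e-6
        t = np.arange(n) * tr
        off = np.cos(2 * np.pi * t / 300.0)
        resid = off - B @ np.linalg.lstsq(B, off, rcond=None)[0]
        assert np.sum(resid ** 2) < 0.25 * np.sum(off ** 2)

    def test_rank_deficiency_names_columns(self, X):
        Xbad = ac.DesignMatrix(
            np.column_stack([X.X, X.column("phonetic")]),
            X.names + ["phonetic_copy"], X.tr_s)
        with pytest.raises(GLMError, match="collinear"):
            ac.fit_glm(make_ts(np.zeros((X.n_volumes, 5))), Xbad)

    def test_length_mismatch_rejected(self, X):
        with pytest.raises(GLMError, match="volumes"):
            ac.fit_glm(make_ts(np.zeros((10, 5)), runs=(10,)), X)


class TestGroupContrast:
    def test_symmetric_values_give_t_zero(self):
        res = ac.group_contrast_test([-0.4, 0.4, -1.1, 1.1])
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_t(self):
        v = np.array([0.3, 0.5, 0.1, 0.4, 0.2, 0.6, 0.35, 0.45, 0.15, 0.55])
        res = ac.group_contrast_test(v)
        t = v.mean() / (v.std(ddof=1) / np.sqrt(len(v)))
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == 9
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 9), abs=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(GLMError):
            ac.group_contrast_test([1.0])

    def test_zero_variance_flagged(self):
        res = ac.group_contrast_test([0.2, 0.2, 0.2])
        assert res.degenerate

    def test_sign_flip_permutation_close_to_parametric(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.1, 1.0, size=12)
        par = ac.group_contrast_test(v)
        perm = ac.group_contrast_test(v, permutation=True, seed=0)
        assert abs(par.p - perm.p) < 0.05


def cells_to_betas(cells):
    """Invert the modulator parameterization: cell means -> betas."""
    # coding: poa +1 alveolar / -1 bilabial, vot +1 long / -1 short
    p_code = np.array([1.0, -1.0])           # (alveolar, bilabial)
    v_code = np.array([-1.0, 1.0])           # (short, long)
    betas = pd.DataFrame(0.0, index=["phonetic", "poa", "vot", "inter"],
                         columns=list(NODES))
    for h, hemi in enumerate(("L", "R")):
        for r, roi in enumerate(("medial", "lateral")):
            node = f"{hemi}_{roi}_AC"
            c = cells[h, r]
            betas.loc["phonetic", node] = c.mean()
            betas.loc["poa", node] = (c * p_code[:, None]).mean()
            betas.loc["vot", node] = (c * v_code[None, :]).mean()
            betas.loc["inter", node] = (c * np.outer(p_code, v_code)).mean()
    return betas


def fit_from_betas(betas):
    X = ac.DesignMatrix(np.zeros((4, 4)), list(betas.index), 2.0)
    return GLMFit(betas=betas, residuals=np.zeros((4, 5)), design=X)


class TestExtractConditionResponses:
    def test_zero_modulators_give_flat_cells(self):
        cells = np.ones((2, 2, 2, 2)) * 1.7
        fit = fit_from_betas(cells_to_betas(cells))
        out = ac.extract_condition_responses(fit)
        assert np.allclose(out, 1.7, atol=1e-12)

    def test_round_trip_from_known_cell_means(self):
        rng = np.random.default_rng(4)
        cells = rng.normal(size=(2, 2, 2, 2))
        fit = fit_from_betas(cells_to_betas(cells))
        out = ac.extract_condition_responses(fit)
        assert np.allclose(out, cells, atol=1e-8)

    def test_swapping_poa_coding_swaps_cells(self):
        rng = np.random.default_rng(5)
        cells = rng.normal(size=(2, 2, 2, 2))
        fit = fit_from_betas(cells_to_betas(cells))
        flipped = ac.ModulatorCoding(poa={"alveolar": -1.0, "bilabial": 1.0})
        out = ac.extract_condition_responses(fit, coding=flipped)
        assert np.allclose(out, cells[:, :, ::-1, :], atol=1e-8)

    def test_missing_regressor_rejected(self):
        betas = cells_to_betas(np.zeros((2, 2, 2, 2))).drop(index="inter")
        with pytest.raises(GLMError, match="inter"):
            ac.extract_condition_responses(fit_from_betas(betas))


class TestRmAnova:
    def test_identical_values_give_zero_f(self):
        cells = np.full((6, 2, 2, 2, 2), 3.3)
        tab = ac.rm_anova(cells)
        assert np.allclose(tab.F, 0.0)

    def test_two_level_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(6)
        cells = rng.normal(size=(10, 2, 2, 2, 2))
        cells[:, 0] += 0.4  # Hemisphere main effect
        tab = ac.rm_anova(cells).set_index("effect")
        marg = cells.mean(axis=(2, 3, 4))
        t, _ = stats.ttest_rel(marg[:, 0], marg[:, 1])
        assert tab.loc["Hemisphere", "F"] == pytest.approx(t ** 2, abs=1e-8)
        # interaction: double difference per subject
        dd = (cells[:, 0, :, :, 0] - cells[:, 0, :, :, 1]
              - cells[:, 1, :, :, 0] + cells[:, 1, :, :, 1]).mean(axis=(1, 2))
        t2, _ = stats.ttest_1samp(dd, 0.0)
        assert tab.loc["Hemisphere x VOT", "F"] == pytest.approx(t2 ** 2,
                                                                 abs=1e-8)

    def test_all_epsilons_one_for_two_level_factors(self):
        rng = np.random.default_rng(7)
        tab = ac.rm_anova(rng.normal(size=(8, 2, 2, 2, 2)))
        assert np.allclose(tab.epsilon, 1.0)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(8)
        cells = rng.normal(size=(9, 2, 2, 2, 2))
        tab = ac.rm_anova(cells).set_index("effect")
        rows = []
        for s in range(9):
            for h, r, p, v in itertools.product(range(2), repeat=4):
                rows.append(dict(subject=s, H=h, R=r, P=p, V=v,
                                 y=cells[s, h, r, p, v]))
        sm = AnovaRM(pd.DataFrame(rows), "y", "subject",
                     within=["H", "R", "P", "V"]).fit().anova_table
        lut = {"H": "Hemisphere", "R": "ROI", "P": "PoA", "V": "VOT"}
        for key, row in sm.iterrows():
            name = " x ".join(lut[k] for k in key.split(":"))
            assert tab.loc[name, "F"] == pytest.approx(row["F Value"],
                                                       abs=1e-8)
            assert tab.loc[name, "p_gg"] == pytest.approx(row["Pr > F"],
                                                          abs=1e-8)

    def test_incomplete_cells_rejected(self):
        cells = np.ones((4, 2, 2, 2, 2))
        cells[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(GLMError, match="missing"):
            ac.rm_anova(cells)
        with pytest.raises(GLMError, match="2 subjects"):
            ac.rm_anova(np.ones((1, 2, 2, 2, 2)))

    def test_posthoc_lsd_pairwise_paired_t(self):
        rng = np.random.default_rng(9)
        cells = rng.normal(size=(7, 2, 2, 2, 2))
        tab = posthoc_lsd(cells, factors=(0, 2),
                          level_names=[("L", "R"), None,
                                       ("alveolar", "bilabial"), None])
        assert len(tab) == 6  # C(4,2) pairwise comparisons
        marg = cells.mean(axis=(2, 4))  # (S, hemi, poa)
        diff = marg[:, 0, 0] - marg[:, 0, 1]
        t, p = stats.ttest_rel(marg[:, 0, 0], marg[:, 0, 1])
        row = tab[(tab.cell_a == "L/alveolar") & (tab.cell_b == "L/bilabial")]
        assert row.t.iloc[0] == pytest.approx(t, abs=1e-10)
        assert row.p_uncorrected.iloc[0] == pytest.approx(p, abs=1e-12)


class TestComposedPipeline:
    def test_noiseless_glm_extract_anova_recovers_cell_means(self, design, X):
        # forward: put known cell means into the parametric regressors,
        # synthesize data, then recover them through fit + extraction
        rng = np.random.default_rng(10)
        cells = rng.normal(loc=1.0, scale=0.3, size=(2, 2, 2, 2))
        betas = cells_to_betas(cells)
        full = pd.DataFrame(0.0, index=X.names, columns=list(NODES))
        full.loc[betas.index] = betas
        ts = make_ts(X.X @ full.to_numpy())
        fit = ac.fit_glm(ts, X)
        out = ac.extract_condition_responses(fit)
        assert np.allclose(out, cells, atol=1e-8)

    def test_percent_signal_change_scaling(self):
        betas = pd.DataFrame([[2.0, 1.0]], index=["phonetic"],
                             columns=["a", "b"])
        psc = percent_signal_change(betas, 100.0)
        assert psc.loc["phonetic", "a"] == pytest.approx(2.0)
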