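"""First-level parametric GLM and group statistics for the ROI series.

The first-level model treats the concatenated runs as one session: a
single "phonetic input" regressor for all non-target trials, parametric
modulators for PoA, VOT and their interaction (mean-centred before HRF
convolution), a separate target-trial nuisance regressor, run-baseline
indicator columns for runs 2..R, and a discrete-cosine high-pass basis
with a 256-s cutoff.  Rest is implicitly modelled, so the phonetic beta
is an increase over baseline.

Group statistics are one-sample t-tests over subjects (optionally
sign-flip permutation), condition-cell reconstruction from the modulator
betas, and a fully within-subject factorial ANOVA with Greenhouse-Geisser
sphericity correction and Fisher-LSD post hocs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dcm import RoiTimeSeries, hemodynamic_response
from .design import ExperimentalDesign, ModulatorCoding, build_input_functions
from .hrf import HRFSpec
from .invert import dct_highpass_basis


class GLMError(ValueError):
    pass


@dataclass
class DesignMatrix:
    X: np.ndarray
    names: list[str]
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def build_design_matrix(design: ExperimentalDesign, hrf: HRFSpec | None = None,
                        highpass_s: float = 256.0, dt_s: float = 0.125,
                        coding: ModulatorCoding | None = None) -> DesignMatrix:
    """Volumes x regressors matrix for the parametric first-level model.

    Columns: hrf-convolved phonetic / poa / vot / inter / target signals,
    run-baseline indicators for runs 2..R, then the DCT high-pass basis
    (its k=0 term is the intercept).
    """
    if design.n_trials == 0:
        raise GLMError("cannot build a design matrix from an empty design")
    hrf = hrf or HRFSpec()
    p = design.params
    if highpass_s <= 2 * p.tr_s:
        raise GLMError("high-pass cutoff must exceed 2*TR")
    inputs = build_input_functions(design, dt_s=dt_s, coding=coding)
    stride = int(round(p.tr_s / dt_s))
    kernel = hrf.kernel(dt_s)
    U = inputs.stack(["phonetic", "poa", "vot", "inter", "target"])
    conv = hemodynamic_response(U, dt_s, kernel, inputs.run_slices(), stride)
    V = conv.shape[0]
    names = ["phonetic", "poa", "vot", "inter", "target"]
    cols = [conv]
    for r in range(2, p.n_runs + 1):
        ind = np.zeros(V)
        ind[(r - 1) * p.volumes_per_run: r * p.volumes_per_run] = 1.0
        cols.append(ind[:, None])
        names.append(f"run_baseline_{r}")
    dct = dct_highpass_basis(V, p.tr_s, highpass_s, include_constant=True)
    cols.append(dct)
    names += [f"dct_{k}" for k in range(dct.shape[1])]
    return DesignMatrix(np.concatenate(cols, axis=1), names, p.tr_s)


@dataclass
class GLMFit:
    betas: pd.DataFrame      # regressors x ROIs
    residuals: np.ndarray    # volumes x ROIs
    design: DesignMatrix

    def beta(self, regressor: str) -> pd.Series:
        return self.betas.loc[regressor]


def fit_glm(ts: RoiTimeSeries, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares per ROI column; errors on rank deficiency."""
    Y = np.asarray(ts.values, float)
    if Y.shape[0] != X.n_volumes:
        raise GLMError(f"time series has {Y.shape[0]} volumes, design matrix "
                       f"{X.n_volumes}")
    rank = np.linalg.matrix_rank(X.X)
    if rank < X.X.shape[1]:
        # name the columns whose projection onto the others is (near) complete
        q, r = np.linalg.qr(X.X)
        bad = [X.names[i] for i in range(X.X.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise GLMError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X.X, Y, rcond=None)
    resid = Y - X.X @ beta
    betas = pd.DataFrame(beta, index=X.names, columns=list(ts.nodes))
    return GLMFit(betas=betas, residuals=resid, design=X)


@dataclass
class ContrastResult:
    values: np.ndarray  # per-subject effect sizes
    t: float
    df: int
    p: float
    degenerate: bool = False


def group_contrast_test(values, permutation: bool = False,
                        n_permutations: int = 10000,
                        seed: int = 0) -> ContrastResult:
    """One-sample t-test of per-subject contrast values against zero.

    With ``permutation=True`` the p-value comes from seeded sign-flipping
    of the subject values instead of the t reference distribution.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise GLMError("need at least 2 subjects for a group test")
    df = len(v) - 1
    if np.allclose(v.std(ddof=1), 0):
        t = 0.0 if np.allclose(v.mean(), 0) else np.inf * np.sign(v.mean())
        return ContrastResult(v, float(t), df, np.nan, degenerate=True)
    t, p = stats.ttest_1samp(v, 0.0)
    if permutation:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(v)))
        null = (signs * v).mean(axis=1) / ((signs * v).std(axis=1, ddof=1)
                                           / np.sqrt(len(v)))
        p = float((np.sum(np.abs(null) >= abs(t)) + 1) / (n_permutations + 1))
    return ContrastResult(v, float(t), df, float(p))


# ---------------------------------------------------------------------------
# condition-cell reconstruction

#: (hemisphere, roi) order of the factorial cell array
HEMI_LEVELS = ("L", "R")
ROI_LEVELS = ("medial", "lateral")
POA_CELL_LEVELS = ("alveolar", "bilabial")
VOT_CELL_LEVELS = ("short", "long")


def extract_condition_responses(fit: GLMFit,
                                coding: ModulatorCoding | None = None
                                ) -> np.ndarray:
    """Reconstruct the 2x2x2x2 condition cells from the modulator betas.

    Returns an array indexed (hemisphere, roi, poa, vot) with levels in
    (L, R) x (medial, lateral) x (alveolar, bilabial) x (short, long).
    The cell response inverts the modulator parameterization:
    ``phonetic + c_poa*poa + c_vot*vot + c_poa*c_vot*inter`` with the
    +-1 codes of the coding in use.  PT is not part of the factorial grid.
    """
    coding = coding or ModulatorCoding()
    for reg in ("phonetic", "poa", "vot", "inter"):
        if reg not in fit.betas.index:
            raise GLMError(f"missing regressor {reg!r} in fit")
    cells = np.zeros((2, 2, 2, 2))
    for (h, hemi), (r, roi) in itertools.product(enumerate(HEMI_LEVELS),
                                                 enumerate(ROI_LEVELS)):
        node = f"{hemi}_{roi}_AC"
        if node not in fit.betas.columns:
            raise GLMError(f"ROI {node!r} absent from fitted series")
        b = fit.betas[node]
        for (i, poa), (j, vot) in itertools.product(
                enumerate(POA_CELL_LEVELS), enumerate(VOT_CELL_LEVELS)):
            cp, cv = coding.poa[poa], coding.vot[vot]
            cells[h, r, i, j] = (b["phonetic"] + cp * b["poa"]
                                 + cv * b["vot"] + cp * cv * b["inter"])
    return cells


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _effect_contrast(levels: int, in_effect: bool) -> np.ndarray:
    """Orthonormal contrast columns (levels x df) or the mean weight."""
    if not in_effect:
        return np.full((levels, 1), 1.0 / levels)
    # Helmert-style orthonormal contrasts spanning deviations from the mean
    H = np.zeros((levels, levels - 1))
    for k in range(1, levels):
        H[:k, k - 1] = 1.0
        H[k, k - 1] = -k
        H[:, k - 1] /= np.linalg.norm(H[:, k - 1])
    return H


def rm_anova(cells: np.ndarray, factor_names: tuple[str, ...] = (
        "Hemisphere", "ROI", "PoA", "VOT")) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA with Greenhouse-Geisser epsilon.

    ``cells`` is subjects x level-grid (e.g. subjects x 2x2x2x2).  For
    every effect the cell array is projected onto orthonormalized contrast
    scores; F is the ratio of the mean squared contrast means to the mean
    within-subject contrast variance, and the GG epsilon is computed from
    the eigenspectrum of the contrast-score covariance (exactly 1 for
    1-df effects, i.e. all-2-level factors).
    """
    cells = np.asarray(cells, float)
    S = cells.shape[0]
    shape = cells.shape[1:]
    if len(shape) != len(factor_names):
        raise GLMError("factor names do not match cell array dimensions")
    if S < 2:
        raise GLMError("need at least 2 subjects")
    if not np.all(np.isfinite(cells)):
        raise GLMError("cells contain missing values")
    flat = cells.reshape(S, -1)
    # numerical floor: sums of squares at rounding-error scale are zero
    tiny = float(np.max(np.abs(flat)) ** 2) * 1e-24 + 1e-300
    rows = []
    for r in range(1, len(factor_names) + 1):
        for combo in itertools.combinations(range(len(factor_names)), r):
            Cs = [_effect_contrast(shape[f], f in combo)
                  for f in range(len(factor_names))]
            C = Cs[0]
            for c in Cs[1:]:
                C = np.kron(C, c)
            Y = flat @ C                       # subjects x df contrast scores
            df1 = C.shape[1]
            ybar = Y.mean(axis=0)
            ss_eff = S * float(ybar @ ybar)
            ss_err = float(np.sum((Y - ybar) ** 2))
            if ss_eff < tiny:
                ss_eff = 0.0
            if ss_err < tiny:
                ss_err = 0.0
            df2 = df1 * (S - 1)
            if ss_err <= 0:
                F = 0.0 if ss_eff <= 0 else np.inf
            else:
                F = (ss_eff / df1) / (ss_err / df2)
            if df1 == 1:
                eps = 1.0
            else:
                Sig = np.cov(Y, rowvar=False)
                ev = np.linalg.eigvalsh(Sig)
                eps = float(ev.sum() ** 2 / (df1 * np.sum(ev ** 2)))
                eps = min(max(eps, 1.0 / df1), 1.0)
            p = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
            rows.append({
                "effect": " x ".join(factor_names[f] for f in combo),
                "F": float(F), "df1": df1, "df2": df2,
                "epsilon": eps, "p_gg": p,
            })
    return pd.DataFrame(rows)


def posthoc_lsd(cells: np.ndarray, factors: tuple[int, ...],
                level_names: list[tuple[str, ...]] | None = None,
                factor_names: tuple[str, ...] = ("Hemisphere", "ROI", "PoA",
                                                 "VOT")) -> pd.DataFrame:
    """Fisher-LSD pairwise comparisons of marginal means.

    Marginalizes the subject cell array over the factors not listed and
    runs uncorrected pairwise paired t-tests between every pair of
    marginal cells (the LSD convention after a significant omnibus
    effect).
    """
    cells = np.asarray(cells, float)
    S = cells.shape[0]
    ndim = cells.ndim - 1
    keep = list(factors)
    other = [a for a in range(ndim) if a not in keep]
    marg = cells.mean(axis=tuple(1 + np.array(other))) if other else cells
    marg = marg.reshape(S, -1)
    labels = []
    grids = [level_names[f] if level_names else
             [f"{factor_names[f]}{i+1}" for i in range(cells.shape[1 + f])]
             for f in keep]
    for combo in itertools.product(*grids):
        labels.append("/".join(combo))
    rows = []
    for a, b in itertools.combinations(range(marg.shape[1]), 2):
        diff = marg[:, a] - marg[:, b]
        t, p = stats.ttest_1samp(diff, 0.0)
        rows.append({"cell_a": labels[a], "cell_b": labels[b],
                     "mean_diff": float(diff.mean()), "t": float(t),
                     "df": S - 1, "p_uncorrected": float(p)})
    return pd.DataFrame(rows)


def percent_signal_change(betas: pd.DataFrame, baseline: pd.Series | float
                          ) -> pd.DataFrame:
    """Scale betas to percent of the per-ROI baseline (beta/baseline*100)."""
    return betas / baseline * 100.0
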