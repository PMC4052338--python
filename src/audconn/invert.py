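"""MAP inversion of a bilinear DCM with Laplace model evidence.

Estimation is damped Gauss-Newton on the log joint under Gaussian priors
(a variational-Laplace scheme with the posterior fixed at its Laplace
approximation): candidate steps are accepted only if the free energy
increases, with Levenberg-Marquardt damping doubled on rejection.  The
free energy is

    F = accuracy - complexity
    accuracy   = log p(y | theta_MAP)          (Gaussian, per-node noise
                                                variance profiled out)
    complexity = KL[ q(theta) || p(theta) ]    (Gaussian posterior/prior)

Observation-level confounds (per-run baseline shifts and a discrete-cosine
high-pass basis) are projected out of both data and predictions, which is
the flat-prior limit for those nuisance coefficients; runs are
concatenated and share the neural parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .dcm import (DCMModel, ParamMap, RoiTimeSeries, _combos,
                  _conv_downsample, _input_matrix, _transition_ops_eig)
from . import _kernels
from .design import InputFunctions
from .hrf import HRFSpec

#: prior variances by parameter kind (weakly informative, DCM-style)
PRIOR_VAR = {"A": 0.25, "B": 0.25, "C": 1.0, "self": 0.0625}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors over the free parameters.

    Structurally masked entries are not free parameters at all, which is
    the zero-variance limit of a prior fixing them at 0.
    """

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be > 0")

    @classmethod
    def default(cls, pmap: ParamMap) -> "PriorSpec":
        var = np.array([PRIOR_VAR[e[0]] for e in pmap.entries])
        return cls(mean=np.zeros(pmap.n_params), var=var)


@dataclass(frozen=True)
class InversionSettings:
    max_iter: int = 128
    tol_nats: float = 1e-4
    damping_init: float = 0.25
    damping_max: float = 1e10
    highpass_s: float = 256.0
    use_confounds: bool = True


@dataclass
class InversionResult:
    """Posterior summary and Laplace free energy of one model fit."""

    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    n_iterations: int
    converged: bool
    f_history: np.ndarray
    sigma2: np.ndarray
    pmap: ParamMap
    priors: PriorSpec
    nodes: tuple[str, ...]
    template: DCMModel = field(repr=False)
    unstable: bool = False

    def posterior_model(self) -> DCMModel:
        """Posterior-mean parameters embedded back into matrices."""
        return self.pmap.unpack(self.posterior_mean, self.template)

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "labels": self.pmap.labels(self.nodes),
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_cov": self.posterior_cov.tolist(),
            "free_energy": self.free_energy,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "sigma2": self.sigma2.tolist(),
        }


def free_energy_components(result: InversionResult) -> tuple[float, float]:
    """(accuracy, complexity) with accuracy - complexity == free_energy."""
    return result.accuracy, result.complexity


def gaussian_kl(mean_q, cov_q, mean_p, var_p) -> float:
    """KL[ N(mean_q, cov_q) || N(mean_p, diag(var_p)) ] in nats."""
    P = len(mean_q)
    d = np.asarray(mean_q) - np.asarray(mean_p)
    prec_p = 1.0 / np.asarray(var_p)
    sign, logdet_q = np.linalg.slogdet(cov_q)
    if sign <= 0:
        raise ValueError("posterior covariance must be positive definite")
    logdet_p = float(np.sum(np.log(var_p)))
    return 0.5 * (float(np.trace(prec_p[:, None] * cov_q)) + float(d @ (prec_p * d))
                  - P + logdet_p - logdet_q)


def confound_matrix(n_volumes: int, tr_s: float, volumes_per_run,
                    highpass_s: float | None = 256.0) -> np.ndarray:
    """Intercept, run-baseline indicators (runs 2..R) and DCT drift basis."""
    cols = [np.ones(n_volumes)]
    edges = np.concatenate([[0], np.cumsum(volumes_per_run)]).astype(int)
    for r in range(1, len(volumes_per_run)):
        ind = np.zeros(n_volumes)
        ind[edges[r]:edges[r + 1]] = 1.0
        cols.append(ind)
    if highpass_s:
        cols.append(dct_highpass_basis(n_volumes, tr_s, highpass_s,
                                       include_constant=False))
    return np.column_stack(cols)


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float,
                       include_constant: bool = True) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than ``cutoff_s``.

    Order K = floor(2 * n * TR / cutoff + 1); component k is
    cos(pi * k * (t + 1/2) / n) (k = 0 is the constant).
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("high-pass cutoff must exceed 2*TR")
    K = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s + 1))
    t = np.arange(n_volumes)
    ks = range(0 if include_constant else 1, max(K, 1))
    cols = [np.cos(np.pi * k * (t + 0.5) / n_volumes) for k in ks]
    if not cols:
        return np.zeros((n_volumes, 0))
    return np.column_stack(cols)


class _Eval(NamedTuple):
    F: float
    accuracy: float
    complexity: float
    sigma2: np.ndarray
    grad: np.ndarray
    Ppost: np.ndarray
    cov: np.ndarray


def _predict_with_jacobian(theta, template, pmap, inputs, kernel, stride,
                           combos):
    """Volume-grid prediction and its (V, P, n) parameter Jacobian."""
    model = pmap.unpack(theta, template)
    ud_u, um_u, idx = combos
    E, d, dE, dd = _transition_ops_eig(model, ud_u, um_u, inputs.dt_s, pmap)
    z0 = np.zeros(model.n)
    kdt = kernel * inputs.dt_s
    # state and sensitivities restart at rest in every run
    y = np.concatenate(
        [_kernels.conv_downsample(
            _kernels.propagate_sens(E, d, dE, dd, idx[sl], z0), kdt, stride)
         for sl in inputs.run_slices()], axis=0)
    V = y.shape[0]
    pred = y[:, :model.n]
    J = y[:, model.n:].reshape(V, pmap.n_params, model.n)
    return pred, J


def invert_model(data: RoiTimeSeries, model: DCMModel, inputs: InputFunctions,
                 priors: PriorSpec | None = None,
                 settings: InversionSettings | None = None,
                 hrf: HRFSpec | None = None) -> InversionResult:
    """Fit a DCM to ROI time series; returns MAP posterior and free energy.

    Deterministic: initialization is at the prior means and there is no
    stochastic step.  Non-convergence within ``max_iter`` returns a result
    with ``converged=False`` rather than raising.
    """
    model.validate()
    settings = settings or InversionSettings()
    hrf = hrf or HRFSpec()
    pmap = ParamMap.from_model(model)
    priors = priors or PriorSpec.default(pmap)
    if len(priors.mean) != pmap.n_params:
        raise ValueError("priors do not cover exactly the unmasked parameters")

    stride = int(round(data.tr_s / inputs.dt_s))
    kernel = hrf.kernel(inputs.dt_s)
    y = np.asarray(data.values, float)
    V, n = y.shape

    if settings.use_confounds:
        X0 = confound_matrix(V, data.tr_s, data.volumes_per_run,
                             settings.highpass_s)
        Q, _ = np.linalg.qr(X0)
        T_eff = V - X0.shape[1]
    else:
        Q = np.zeros((V, 0))
        T_eff = V

    def project(M):
        return M - Q @ (Q.T @ M)

    y_perp = project(y)
    floor = 1e-8 * np.maximum(y_perp.var(axis=0), 1e-12) + 1e-12
    prec0 = 1.0 / priors.var
    mu0 = priors.mean
    combos = _combos(*_input_matrix(model, inputs))

    def evaluate(theta) -> _Eval | None:
        pred, J = _predict_with_jacobian(theta, model, pmap, inputs, kernel,
                                         stride, combos)
        if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(J))):
            return None
        e = y_perp - project(pred)
        Jp = project(J.reshape(V, -1)).reshape(V, pmap.n_params, n)
        sse = np.sum(e ** 2, axis=0)
        sigma2 = np.maximum(sse / max(T_eff, 1), floor)
        accuracy = float(np.sum(-0.5 * T_eff * np.log(2 * np.pi * sigma2)
                                - 0.5 * sse / sigma2))
        H = np.zeros((pmap.n_params, pmap.n_params))
        g = np.zeros(pmap.n_params)
        for k in range(n):
            Jk = np.ascontiguousarray(Jp[:, :, k])
            H += (Jk.T @ Jk) / sigma2[k]
            g += (Jk.T @ e[:, k]) / sigma2[k]
        d = theta - mu0
        g -= prec0 * d
        Ppost = H + np.diag(prec0)
        jitter = 0.0
        for _ in range(8):
            try:
                c = cho_factor(Ppost + jitter * np.eye(pmap.n_params))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-8)
                warnings.warn("singular curvature; ridge-regularizing",
                              RuntimeWarning, stacklevel=2)
        cov = cho_solve(c, np.eye(pmap.n_params))
        cov = 0.5 * (cov + cov.T)
        complexity = gaussian_kl(theta, cov, mu0, priors.var)
        F = accuracy - complexity
        if not np.isfinite(F):
            return None
        return _Eval(F, accuracy, complexity, sigma2, g, Ppost, cov)

    theta = mu0.copy()
    ev = evaluate(theta)
    if ev is None:
        raise RuntimeError("model prediction not finite at prior means")
    history = [ev.F]
    nu = settings.damping_init
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        # Newton decrement: expected gain of an undamped step; if it is
        # below tolerance no proposal can improve F noticeably
        if 0.5 * float(ev.grad @ (ev.cov @ ev.grad)) < settings.tol_nats:
            converged = True
            break
        accepted = False
        ev_new = None
        for _ in range(24):
            if nu > settings.damping_max:
                break
            damp = np.diag(nu * np.abs(np.diag(ev.Ppost)) + nu * 1e-8)
            try:
                step = np.linalg.solve(ev.Ppost + damp, ev.grad)
            except np.linalg.LinAlgError:
                nu = max(nu * 2, 1e-3)
                continue
            cand = theta + step
            ev_new = evaluate(cand)
            if ev_new is not None and ev_new.F > ev.F:
                accepted = True
                # gain ratio: relax damping only when the local quadratic
                # model predicted the improvement well
                predicted = float(ev.grad @ step - 0.5 * step @ (ev.Ppost @ step))
                rho = (ev_new.F - ev.F) / predicted if predicted > 0 else 1.0
                if rho > 0.5:
                    nu = max(nu / 4, 1e-8)
                break
            if (ev_new is not None and nu >= 1.0
                    and abs(ev_new.F - ev.F) < settings.tol_nats):
                break  # heavily damped step cannot improve F: stalled
            nu = max(nu * 2, 1e-3)
        if not accepted:
            # stalled at a (local) optimum of the damped ascent
            converged = True
            break
        dF = ev_new.F - ev.F
        theta, ev = cand, ev_new
        history.append(ev.F)
        if dF < settings.tol_nats:
            converged = True
            break

    return InversionResult(
        posterior_mean=theta, posterior_cov=ev.cov, free_energy=ev.F,
        accuracy=ev.accuracy, complexity=ev.complexity, n_iterations=it,
        converged=converged, f_history=np.array(history), sigma2=ev.sigma2,
        pmap=pmap, priors=priors, nodes=model.nodes, template=model,
        unstable=data.unstable)
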