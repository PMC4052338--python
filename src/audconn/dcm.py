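"""Bilinear dynamic causal model: containers, integration, BOLD prediction.

The neural state equation is ``dz/dt = (A + sum_j u_j B_j) z + C u`` with
``z`` the per-node activity, ``u`` the experimental inputs (a driving
"phonetic input" plus condition modulators), ``A`` the fixed coupling,
``B_j`` the modulator-dependent coupling change and ``C`` the input
weights (all in Hz).  Observed BOLD is the neural trajectory convolved
with a canonical HRF and sampled on the volume grid.

Because the inputs are piecewise constant on the micro-time grid, the
system is linear time-invariant within each step; integration uses the
exact per-step transition ``expm`` of the augmented system, computed once
per distinct input combination (there are only a handful: off, alveolar
stimulation, bilabial stimulation, ...).  Parameter sensitivities for the
inversion come from the Frechet derivative of the same matrix
exponential, so the Jacobian is exact rather than finite-differenced.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, expm_frechet
from scipy.signal import fftconvolve

from . import _kernels
from .design import InputFunctions
from .hrf import HRFSpec

DEFAULT_NODES = ("L_medial_AC", "L_lateral_AC", "L_PT",
                 "R_medial_AC", "R_lateral_AC")

#: MNI peak coordinates the five ROIs stand for (metadata only)
ROI_MNI = {
    "L_lateral_AC": (-65, -12, 3),
    "L_medial_AC": (-48, -15, 6),
    "L_PT": (-60, -34, 15),
    "R_medial_AC": (50, -13, 1),
    "R_lateral_AC": (63, -22, 7),
}


class ModelError(ValueError):
    """Raised for structurally invalid DCMs."""


@dataclass
class DCMModel:
    """A bilinear DCM: nodes, A/B/C matrices and their structural masks.

    Convention: ``A[i, j]`` is the influence of node ``j`` on node ``i``
    (row = target, column = source).  Entries outside the masks must be
    exactly zero; the diagonal of ``A`` (self-decay) is strictly negative
    and is not covered by ``mask_A``.
    """

    nodes: tuple[str, ...]
    A: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    mask_A: np.ndarray
    mask_B: dict[str, np.ndarray]
    mask_C: np.ndarray
    driving: tuple[str, ...] = ("phonetic",)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def modulators(self) -> tuple[str, ...]:
        return tuple(self.B)

    def validate(self) -> None:
        n = self.n
        off = ~np.eye(n, dtype=bool)
        if np.any(self.A[off & ~self.mask_A] != 0):
            raise ModelError("A has nonzero entries outside mask_A")
        if np.any(np.diag(self.A) >= 0):
            raise ModelError("diagonal of A must be strictly negative")
        for name, Bm in self.B.items():
            if np.any(Bm[~self.mask_B[name]] != 0):
                raise ModelError(f"B[{name}] has nonzero entries outside its mask")
        if np.any(self.C[~self.mask_C] != 0):
            raise ModelError("C has nonzero entries outside mask_C")

    def copy(self) -> "DCMModel":
        return DCMModel(
            self.nodes, self.A.copy(), {k: v.copy() for k, v in self.B.items()},
            self.C.copy(), self.mask_A.copy(),
            {k: v.copy() for k, v in self.mask_B.items()},
            self.mask_C.copy(), self.driving)

    # -- JSON round trip --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": list(self.nodes),
            "driving": list(self.driving),
            "modulators": list(self.B),
            "A": self.A.tolist(),
            "B": {k: v.tolist() for k, v in self.B.items()},
            "C": self.C.tolist(),
            "mask_A": self.mask_A.astype(int).tolist(),
            "mask_B": {k: v.astype(int).tolist() for k, v in self.mask_B.items()},
            "mask_C": self.mask_C.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DCMModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            nodes=tuple(doc["nodes"]),
            A=np.asarray(doc["A"], float),
            B={k: np.asarray(doc["B"][k], float) for k in doc["modulators"]},
            C=np.asarray(doc["C"], float),
            mask_A=np.asarray(doc["mask_A"], bool),
            mask_B={k: np.asarray(doc["mask_B"][k], bool) for k in doc["modulators"]},
            mask_C=np.asarray(doc["mask_C"], bool),
            driving=tuple(doc["driving"]),
        )


@dataclass
class NeuralState:
    """Per-node neural trajectory on the micro-time grid."""

    z: np.ndarray  # (n_samples, n_nodes), z[t] = state at time t*dt
    dt_s: float
    unstable: bool = False


@dataclass
class RoiTimeSeries:
    """BOLD samples (volumes x ROIs) with TR and run boundaries."""

    values: np.ndarray
    nodes: tuple[str, ...]
    tr_s: float
    volumes_per_run: tuple[int, ...]
    unstable: bool = False

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def run_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.volumes_per_run)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        t = np.arange(self.n_volumes) * self.tr_s
        df = pd.DataFrame(self.values, columns=list(self.nodes))
        df.insert(0, "time", t)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g",
                  lineterminator="\n")
        if sidecar is not None:
            doc = {"tr_s": self.tr_s, "nodes": list(self.nodes),
                   "volumes_per_run": list(self.volumes_per_run)}
            Path(sidecar).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path) -> "RoiTimeSeries":
        doc = json.loads(Path(sidecar).read_text())
        df = pd.read_csv(path, sep="\t")
        return cls(df[doc["nodes"]].to_numpy(float), tuple(doc["nodes"]),
                   float(doc["tr_s"]), tuple(doc["volumes_per_run"]))


# ---------------------------------------------------------------------------
# parameter packing

@dataclass(frozen=True)
class ParamMap:
    """Flat indexing of the free (unmasked) parameters of a DCM.

    Kinds: ``A`` off-diagonal coupling, ``self`` log-scale self-decay
    (``A_ii = -0.5 * exp(theta)``), ``B`` modulatory coupling, ``C`` input
    weight.  Structurally masked entries never appear here, which is the
    degenerate (zero-variance) limit of a prior pinning them at zero.
    """

    entries: tuple[tuple, ...]  # ("A", i, j) | ("self", i) | ("B", mod, i, j) | ("C", i, k)

    @classmethod
    def from_model(cls, model: DCMModel) -> "ParamMap":
        n = model.n
        ent: list[tuple] = []
        for i in range(n):
            for j in range(n):
                if i != j and model.mask_A[i, j]:
                    ent.append(("A", i, j))
        for i in range(n):
            ent.append(("self", i))
        for mod in model.modulators:
            m = model.mask_B[mod]
            for i in range(n):
                for j in range(n):
                    if m[i, j]:
                        ent.append(("B", mod, i, j))
        for i in range(n):
            for k in range(model.C.shape[1]):
                if model.mask_C[i, k]:
                    ent.append(("C", i, k))
        return cls(tuple(ent))

    @property
    def n_params(self) -> int:
        return len(self.entries)

    def labels(self, nodes: Sequence[str]) -> list[str]:
        out = []
        for e in self.entries:
            if e[0] == "A":
                out.append(f"A:{nodes[e[2]]}->{nodes[e[1]]}")
            elif e[0] == "self":
                out.append(f"self:{nodes[e[1]]}")
            elif e[0] == "B":
                out.append(f"B[{e[1]}]:{nodes[e[3]]}->{nodes[e[2]]}")
            else:
                out.append(f"C:u{e[2]}->{nodes[e[1]]}")
        return out

    def pack(self, model: DCMModel) -> np.ndarray:
        """Model matrices -> flat parameter vector."""
        th = np.empty(self.n_params)
        for p, e in enumerate(self.entries):
            if e[0] == "A":
                th[p] = model.A[e[1], e[2]]
            elif e[0] == "self":
                a = model.A[e[1], e[1]]
                th[p] = np.log(-a / 0.5)
            elif e[0] == "B":
                th[p] = model.B[e[1]][e[2], e[3]]
            else:
                th[p] = model.C[e[1], e[2]]
        return th

    def unpack(self, theta: np.ndarray, model: DCMModel) -> DCMModel:
        """Flat vector -> model with the same structure."""
        out = model.copy()
        for p, e in enumerate(self.entries):
            if e[0] == "A":
                out.A[e[1], e[2]] = theta[p]
            elif e[0] == "self":
                out.A[e[1], e[1]] = -0.5 * np.exp(theta[p])
            elif e[0] == "B":
                out.B[e[1]][e[2], e[3]] = theta[p]
            else:
                out.C[e[1], e[2]] = theta[p]
        return out


# ---------------------------------------------------------------------------
# transition operators

def _input_matrix(model: DCMModel, inputs: InputFunctions) -> tuple[np.ndarray, np.ndarray]:
    u_drive = inputs.stack(model.driving)
    u_mod = (inputs.stack(model.modulators)
             if model.modulators else np.zeros((inputs.n_samples, 0)))
    return u_drive, u_mod


def _effective_matrices(model: DCMModel, ud: np.ndarray, um: np.ndarray):
    """M = A + sum_j u_j B_j and c = C u for one input combination."""
    M = model.A.copy()
    for j, mod in enumerate(model.modulators):
        M = M + um[j] * model.B[mod]
    c = model.C @ ud
    return M, c


def _combos(u_drive: np.ndarray, u_mod: np.ndarray):
    U = np.column_stack([u_drive, u_mod])
    uniq, idx = np.unique(U, axis=0, return_inverse=True)
    md = u_drive.shape[1]
    return uniq[:, :md], uniq[:, md:], idx.astype(np.int64)


def check_stability(model: DCMModel, inputs: InputFunctions) -> bool:
    """True if A + sum u_j B_j is Hurwitz for every realized input combo."""
    _, u_mod = _input_matrix(model, inputs)
    for um in np.unique(u_mod, axis=0):
        M, _ = _effective_matrices(model, np.zeros(len(model.driving)), um)
        if np.max(np.linalg.eigvals(M).real) >= 0:
            return False
    return True


def _transition_ops(model: DCMModel, ud_u: np.ndarray, um_u: np.ndarray,
                    dt: float, pmap: ParamMap | None = None):
    """Exact one-step transitions (and their parameter derivatives).

    Uses the augmented system d/dt [z; 1] = [[M, c], [0, 0]] [z; 1]; the
    top-left/top-right blocks of its exponential are E and d.  With
    ``pmap``, directional Frechet derivatives give dE and dd exactly.
    """
    n = model.n
    K = ud_u.shape[0]
    E = np.empty((K, n, n))
    d = np.empty((K, n))
    need = pmap is not None
    P = pmap.n_params if need else 0
    dE = np.zeros((K, P, n, n))
    dd = np.zeros((K, P, n))
    for k in range(K):
        M, c = _effective_matrices(model, ud_u[k], um_u[k])
        Maug = np.zeros((n + 1, n + 1))
        Maug[:n, :n] = M
        Maug[:n, n] = c
        Eaug = expm(Maug * dt)
        E[k] = Eaug[:n, :n]
        d[k] = Eaug[:n, n]
        if not need:
            continue
        for p, e in enumerate(pmap.entries):
            D = np.zeros((n + 1, n + 1))
            if e[0] == "A":
                D[e[1], e[2]] = 1.0
            elif e[0] == "self":
                D[e[1], e[1]] = model.A[e[1], e[1]]  # d(-0.5 e^th)/dth = A_ii
            elif e[0] == "B":
                j = model.modulators.index(e[1])
                D[e[2], e[3]] = um_u[k][j]
            else:  # C
                D[e[1], n] = ud_u[k][e[2]]
            dEaug = expm_frechet(Maug * dt, D * dt, compute_expm=False)
            dE[k, p] = dEaug[:n, :n]
            dd[k, p] = dEaug[:n, n]
    return (E, d, dE, dd) if need else (E, d)


def _transition_ops_eig(model: DCMModel, ud_u: np.ndarray, um_u: np.ndarray,
                        dt: float, pmap: ParamMap):
    """Eigen-based variant of `_transition_ops` with derivatives.

    Every free parameter perturbs the augmented generator in a single
    entry, so its Frechet derivative is ``V ((V^-1 e_r e_c^T V) * Phi) V^-1``
    with ``Phi`` the divided-difference table of the eigenvalue
    exponentials - two small matmuls per direction instead of a full
    `expm_frechet`.  Falls back to the scaling-and-squaring route when the
    eigenbasis is ill-conditioned.
    """
    n = model.n
    K = ud_u.shape[0]
    P = pmap.n_params
    E = np.empty((K, n, n))
    d = np.empty((K, n))
    dE = np.zeros((K, P, n, n))
    dd = np.zeros((K, P, n))
    mod_index = {m: j for j, m in enumerate(model.modulators)}
    for k in range(K):
        M, c = _effective_matrices(model, ud_u[k], um_u[k])
        X = np.zeros((n + 1, n + 1))
        X[:n, :n] = M
        X[:n, n] = c
        X *= dt
        lam, Vv = np.linalg.eig(X)
        ok = np.isfinite(Vv).all()
        if ok:
            cond = np.linalg.cond(Vv)
            ok = np.isfinite(cond) and cond < 1e6
        if not ok:  # defective generator: use the robust path for this combo
            sub = _transition_ops(model, ud_u[k:k + 1], um_u[k:k + 1], dt,
                                  pmap=pmap)
            E[k], d[k], dE[k], dd[k] = sub[0][0], sub[1][0], sub[2][0], sub[3][0]
            continue
        Vinv = np.linalg.inv(Vv)
        el = np.exp(lam)
        Eaug = ((Vv * el) @ Vinv).real
        E[k] = Eaug[:n, :n]
        d[k] = Eaug[:n, n]
        mean = 0.5 * (lam[:, None] + lam[None, :])
        half = 0.5 * (lam[:, None] - lam[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(np.abs(half) < 1e-8, 1.0, np.sinh(half) / half)
        Phi = np.exp(mean) * ratio
        for p, e in enumerate(pmap.entries):
            if e[0] == "A":
                r, col, alpha = e[1], e[2], 1.0
            elif e[0] == "self":
                r, col, alpha = e[1], e[1], model.A[e[1], e[1]]
            elif e[0] == "B":
                r, col, alpha = e[2], e[3], um_u[k][mod_index[e[1]]]
            else:
                r, col, alpha = e[1], n, ud_u[k][e[2]]
            if alpha == 0.0:
                continue
            inner = np.outer(Vinv[:, r], Vv[col, :]) * Phi * (alpha * dt)
            L = (Vv @ inner @ Vinv).real
            dE[k, p] = L[:n, :n]
            dd[k, p] = L[:n, n]
    return E, d, dE, dd


def _conv_downsample(z: np.ndarray, dt_s: float, kernel: np.ndarray,
                     run_slices: Sequence[slice], stride: int) -> np.ndarray:
    """`hemodynamic_response` computed only at the volume-grid samples.

    Polyphase decomposition of the strided convolution
    ``y[v] = sum_tau k[tau] z[v*stride - tau]``: splitting ``tau`` into
    ``a*stride + b`` turns the whole computation into one small GEMM over
    the phase axis plus shifted accumulations, so work scales with
    volumes (not micro-time samples) and nothing large is copied.
    Matches the FFT route to rounding error.
    """
    s = stride
    k = kernel * dt_s
    A = int(np.ceil((len(k) + 1) / s))
    kp = np.zeros(A * s)
    kp[:len(k)] = k
    # W1[a, j] = k[(a+1)*s - j] pairs with phase j >= 1; the j = 0 phase
    # (b = 0 taps, k[a*s]) needs a shifted accumulation and is kept apart.
    W1 = np.zeros((A, s))
    for a in range(A):
        for j in range(1, s):
            if (a + 1) * s - j < len(kp):
                W1[a, j] = kp[(a + 1) * s - j]
    k0 = kp[::s]
    out = []
    for sl in run_slices:
        zr = z[sl]
        T, C = zr.shape
        V = T // s
        Zp = np.concatenate([np.zeros((s, C)), zr]).reshape(V + 1, s, C)
        T1 = np.matmul(W1, Zp)  # (V+1, A, C) batched over volumes
        y = np.zeros((V, C))
        t2 = Zp[:, 0, :]
        for a in range(A):
            y[a:] += T1[: V - a, a]
            if k0[a] != 0.0:
                lo = max(a - 1, 0)
                y[lo:] += k0[a] * t2[lo - a + 1: V - a + 1]
        out.append(y)
    return np.concatenate(out, axis=0)


def integrate_states(model: DCMModel, inputs: InputFunctions,
                     z0: np.ndarray | None = None,
                     warn_unstable: bool = True) -> NeuralState:
    """Integrate the bilinear state equation over the input functions.

    Exact for the piecewise-constant inputs (per-step matrix exponential).
    An input combination making the effective coupling non-Hurwitz flags
    the result as unstable (with a warning) but still integrates.
    """
    model.validate()
    z0 = np.zeros(model.n) if z0 is None else np.asarray(z0, float)
    u_drive, u_mod = _input_matrix(model, inputs)
    ud_u, um_u, idx = _combos(u_drive, u_mod)
    unstable = False
    for k in range(ud_u.shape[0]):
        M, _ = _effective_matrices(model, ud_u[k], um_u[k])
        if np.max(np.linalg.eigvals(M).real) >= 0:
            unstable = True
    if unstable and warn_unstable:
        warnings.warn("effective coupling matrix is not stable for at least "
                      "one input combination", RuntimeWarning, stacklevel=2)
    E, d = _transition_ops(model, ud_u, um_u, inputs.dt_s)
    # runs are separate acquisitions: the state restarts at z0 in each
    Z = np.concatenate([_kernels.propagate(E, d, idx[sl], z0)
                        for sl in inputs.run_slices()], axis=0)
    return NeuralState(z=Z, dt_s=inputs.dt_s, unstable=unstable)


def hemodynamic_response(z: np.ndarray, dt_s: float, kernel: np.ndarray,
                         run_slices: Sequence[slice], stride: int) -> np.ndarray:
    """Convolve neural trajectories with the HRF per run, sample volumes.

    Convolution is run-wise (no bleed across run boundaries) and scaled by
    ``dt_s`` to approximate the continuous integral; volume ``v`` samples
    micro index ``v*stride``.
    """
    out = []
    k = kernel[:, None] if z.ndim > 1 else kernel
    for sl in run_slices:
        zr = z[sl]
        y = fftconvolve(zr, k, axes=0)[: zr.shape[0]] * dt_s
        out.append(y[::stride])
    return np.concatenate(out, axis=0)


def forward_predict(model: DCMModel, inputs: InputFunctions,
                    hrf: HRFSpec | None = None, tr_s: float = 2.0,
                    z0: np.ndarray | None = None) -> RoiTimeSeries:
    """Predicted ROI BOLD: integrate states, convolve with HRF, downsample."""
    hrf = hrf or HRFSpec()
    state = integrate_states(model, inputs, z0=z0)
    stride = int(round(tr_s / inputs.dt_s))
    kernel = hrf.kernel(inputs.dt_s)
    y = hemodynamic_response(state.z, inputs.dt_s, kernel,
                             inputs.run_slices(), stride)
    vols = y.shape[0] // inputs.n_runs
    return RoiTimeSeries(values=y, nodes=model.nodes, tr_s=tr_s,
                         volumes_per_run=(vols,) * inputs.n_runs,
                         unstable=state.unstable)
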