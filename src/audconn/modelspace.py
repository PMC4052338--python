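"""Constrained connectivity, the 16-model modulation space, BMS and BMA.

The 5-node auditory network (left/right medial and lateral auditory
cortex plus left planum temporale) is wired by a simple rule: each AC
node connects reciprocally to its within-hemisphere neighbour, to its
contralateral homolog, and to PT - but not to its non-homolog across
hemispheres.  That yields 8 reciprocal pairs = 16 directed inter-regional
connections.  The modulation space puts the condition modulator (place of
articulation) on exactly one of those connections per model, giving 16
candidate models that share A and C.

Bayesian model selection is provided in fixed-effects form (softmax of
log evidences summed over subjects, uniform model prior) and
random-effects form (the variational Dirichlet scheme over population
model frequencies, with sampled exceedance probabilities).  Bayesian
model averaging weights connection-wise posterior means by model
posterior probability, with connections absent from a model contributing
zero.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, logsumexp

from .dcm import DCMModel, ParamMap
from .invert import InversionResult


class ModelSpaceError(ValueError):
    pass


@dataclass
class ConnectivityMask:
    """Permitted directed inter-regional connections (row=target, col=source)."""

    matrix: np.ndarray
    nodes: tuple[str, ...]

    @property
    def n_connections(self) -> int:
        return int(self.matrix.sum())

    def connections(self) -> list[tuple[int, int]]:
        """(target, source) index pairs, row-major order."""
        return [(i, j) for i in range(len(self.nodes))
                for j in range(len(self.nodes)) if self.matrix[i, j]]


_ROLE_RE = re.compile(r"^(L|R)_(medial|lateral)_AC$")


def _node_role(label: str) -> tuple[str, str]:
    """(hemisphere, role) with role in {medial, lateral, PT}."""
    m = _ROLE_RE.match(label)
    if m:
        return m.group(1), m.group(2)
    if label.endswith("_PT"):
        return label.split("_")[0], "PT"
    raise ModelSpaceError(f"cannot parse node role from label {label!r}")


def build_connectivity_mask(nodes: Sequence[str]) -> ConnectivityMask:
    """Apply the neighbour + homolog + PT wiring rule to the node labels.

    Reciprocal connections: medial<->lateral within hemisphere,
    medial<->medial and lateral<->lateral across hemispheres, and every AC
    node<->PT.  Non-homolog cross-hemisphere AC connections are excluded.
    """
    roles = [_node_role(n) for n in nodes]
    n = len(nodes)
    M = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            (hi, ri), (hj, rj) = roles[i], roles[j]
            if ri == "PT" or rj == "PT":
                M[i, j] = True
            elif hi == hj and ri != rj:
                M[i, j] = True  # within-hemisphere neighbours
            elif hi != hj and ri == rj:
                M[i, j] = True  # contralateral homologs
    return ConnectivityMask(M, tuple(nodes))


@dataclass
class ModelSpace:
    """One member model per permitted connection, differing only in mask_B."""

    mask: ConnectivityMask
    input_nodes: tuple[str, ...]
    members: list[DCMModel]
    modulator: str

    @property
    def n_models(self) -> int:
        return len(self.members)

    def connection_labels(self) -> list[str]:
        nodes = self.mask.nodes
        return [f"{nodes[j]}->{nodes[i]}" for i, j in self.mask.connections()]


def enumerate_poa_models(mask: ConnectivityMask,
                         inputs_to: Sequence[str] | None = None,
                         modulator: str = "poa") -> ModelSpace:
    """The modulation model space: each member B-permits one connection.

    All members share the A-mask (the full connectivity rule) and the
    C-mask (driving input to the four AC nodes by default).
    """
    nodes = mask.nodes
    n = len(nodes)
    if inputs_to is None:
        inputs_to = tuple(x for x in nodes if x.endswith("_AC"))
    unknown = set(inputs_to) - set(nodes)
    if unknown:
        raise ModelSpaceError(f"input nodes not in network: {sorted(unknown)}")
    mask_C = np.zeros((n, 1), dtype=bool)
    for lab in inputs_to:
        mask_C[nodes.index(lab), 0] = True
    members = []
    for (i, j) in mask.connections():
        mb = np.zeros((n, n), dtype=bool)
        mb[i, j] = True
        members.append(DCMModel(
            nodes=tuple(nodes),
            A=np.diag(np.full(n, -0.5)),
            B={modulator: np.zeros((n, n))},
            C=np.zeros((n, 1)),
            mask_A=mask.matrix.copy(),
            mask_B={modulator: mb},
            mask_C=mask_C.copy(),
        ))
    return ModelSpace(mask=mask, input_nodes=tuple(inputs_to),
                      members=members, modulator=modulator)


# ---------------------------------------------------------------------------
# Bayesian model selection

@dataclass
class BMSResult:
    """Model posterior probabilities over a compared model set.

    Fixed effects: ``pP`` is the softmax of log evidences summed over
    subjects.  Random effects: ``pP`` holds the expected model
    frequencies, with the Dirichlet parameters and exceedance
    probabilities alongside.
    """

    pP: np.ndarray
    winner: int
    mode: str
    summed_log_evidence: np.ndarray | None = None
    alpha: np.ndarray | None = None
    exceedance: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = float(self.pP.sum())
        if not np.isclose(s, 1.0, atol=1e-10):
            raise ModelSpaceError(f"posterior probabilities sum to {s}, not 1")


def bms(log_evidences: np.ndarray, mode: str = "ffx",
        seed: int = 0, n_exceedance_samples: int = 20000) -> BMSResult:
    """Bayesian model selection from a subjects x models evidence matrix.

    ``mode='ffx'``: treat subjects as replicates of one model (sum log
    evidences, softmax under a uniform model prior).  ``mode='rfx'``:
    variational Dirichlet estimate of population model frequencies;
    exceedance probabilities are estimated by seeded Dirichlet sampling.
    Ties break toward the lowest model index.
    """
    L = np.atleast_2d(np.asarray(log_evidences, float))
    if not np.all(np.isfinite(L)):
        raise ModelSpaceError("log evidences must be finite")
    S, M = L.shape
    if M < 2:
        raise ModelSpaceError("need at least 2 models")
    if mode == "ffx":
        summed = L.sum(axis=0)
        pP = np.exp(summed - logsumexp(summed))
        pP /= pP.sum()
        return BMSResult(pP=pP, winner=int(np.argmax(pP)), mode="ffx",
                         summed_log_evidence=summed)
    if mode != "rfx":
        raise ModelSpaceError(f"unknown BMS mode {mode!r}")
    alpha0 = np.ones(M)
    alpha = alpha0.copy()
    for _ in range(200):
        lg = L + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-8:
            alpha = alpha_new
            break
        alpha = alpha_new
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_exceedance_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=M) / draws.shape[0]
    return BMSResult(pP=freq / freq.sum(), winner=int(np.argmax(freq)),
                     mode="rfx", alpha=alpha, exceedance=xp)


def family_compare(log_evidences: np.ndarray,
                   families: Mapping[str, Sequence[int]],
                   mode: str = "ffx", seed: int = 0) -> dict[str, float]:
    """Posterior probability mass per model family.

    ``families`` must partition the model indices.  Fixed effects: the
    evidence mass of a family is the sum of its members' exponentiated
    summed log evidences, normalized across families.  Random effects:
    summed expected model frequencies from the Dirichlet scheme.
    """
    L = np.atleast_2d(np.asarray(log_evidences, float))
    M = L.shape[1]
    idx = [i for members in families.values() for i in members]
    if sorted(idx) != list(range(M)):
        raise ModelSpaceError("families must partition the model indices")
    if mode == "ffx":
        summed = L.sum(axis=0)
        log_mass = {name: logsumexp(summed[list(members)])
                    for name, members in families.items()}
        norm = logsumexp(np.array(list(log_mass.values())))
        return {name: float(np.exp(v - norm)) for name, v in log_mass.items()}
    res = bms(L, mode="rfx", seed=seed)
    return {name: float(res.pP[list(members)].sum())
            for name, members in families.items()}


# ---------------------------------------------------------------------------
# Bayesian model averaging

@dataclass
class BMAResult:
    """Probability-weighted average connection strengths."""

    nodes: tuple[str, ...]
    A: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    weights: np.ndarray

    def flatten(self, mask_A: np.ndarray, mask_B: Mapping[str, np.ndarray],
                mask_C: np.ndarray) -> np.ndarray:
        """Vector of [A offdiag, B, C] entries over the given masks."""
        parts = [self.A[mask_A]]
        for k in sorted(mask_B):
            parts.append(self.B[k][mask_B[k]])
        parts.append(self.C[mask_C])
        return np.concatenate(parts)


def _embed(result: InversionResult, theta: np.ndarray,
           modulators: Sequence[str]) -> tuple[np.ndarray, dict, np.ndarray]:
    n = len(result.nodes)
    A = np.zeros((n, n))
    B = {m: np.zeros((n, n)) for m in modulators}
    C = np.zeros_like(result.template.C, dtype=float)
    for p, e in enumerate(result.pmap.entries):
        if e[0] == "A":
            A[e[1], e[2]] = theta[p]
        elif e[0] == "self":
            A[e[1], e[1]] = -0.5 * np.exp(theta[p])
        elif e[0] == "B":
            B[e[1]][e[2], e[3]] = theta[p]
        else:
            C[e[1], e[2]] = theta[p]
    return A, B, C


def bma(fits: Sequence[Sequence[InversionResult]], weights: BMSResult,
        n_samples: int = 1, seed: int = 0) -> BMAResult:
    """Bayesian model averaging of connection strengths.

    ``fits`` is subjects x models (a single subject's list may be passed
    as ``[fits_for_subject]``).  With ``n_samples == 1`` the average is
    the deterministic pP-weighted mean of posterior means; with more
    samples, models and parameters are sampled from the weighted posterior
    mixture.  A connection absent from every model averages to exactly 0.
    """
    fits = [list(f) for f in fits]
    M = len(weights.pP)
    if any(len(f) != M for f in fits):
        raise ModelSpaceError("fits per subject do not align with BMS weights")
    first = fits[0][0]
    nodes = first.nodes
    modulators = first.template.modulators
    rng = np.random.default_rng(seed)
    n = len(nodes)
    A = np.zeros((n, n))
    B = {m: np.zeros((n, n)) for m in modulators}
    C = np.zeros_like(first.template.C, dtype=float)
    for subj in fits:
        if n_samples == 1:
            for m, fit in enumerate(subj):
                a, b, c = _embed(fit, fit.posterior_mean, modulators)
                A += weights.pP[m] * a
                C += weights.pP[m] * c
                for k in modulators:
                    B[k] += weights.pP[m] * b[k]
        else:
            counts = rng.multinomial(n_samples, weights.pP)
            for m, cnt in enumerate(counts):
                if cnt == 0:
                    continue
                fit = subj[m]
                draws = rng.multivariate_normal(
                    fit.posterior_mean, fit.posterior_cov, size=cnt)
                for th in draws:
                    a, b, c = _embed(fit, th, modulators)
                    A += a / n_samples
                    C += c / n_samples
                    for k in modulators:
                        B[k] += b[k] / n_samples
    S = len(fits)
    A /= S
    C /= S
    for k in modulators:
        B[k] /= S
    return BMAResult(nodes=nodes, A=A, B=B, C=C, weights=weights.pP.copy())
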