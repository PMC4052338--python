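"""Synthetic multi-subject ROI BOLD datasets with known ground truth.

Stands in for the (undeposited) 7T data: each subject gets an independent
seeded realization of the block design, neural dynamics from a
ground-truth DCM with subject-level parameter jitter, BOLD through the
canonical HRF, and additive structured noise (AR(1)-filtered Gaussian
plus a slow cosine drift) scaled to a target SNR.  SNR is defined as the
standard deviation of the stimulus-locked signal over the standard
deviation of the AR+white noise, both at the volume grid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .dcm import (DCMModel, DEFAULT_NODES, RoiTimeSeries, check_stability,
                  forward_predict)
from .design import (DesignParams, ExperimentalDesign, build_input_functions,
                     generate_design)
from .hrf import HRFSpec
from .modelspace import build_connectivity_mask


@dataclass
class NoiseSpec:
    """Observation-noise structure at the volume grid.

    ``ar_coef`` is the lag-1 autocorrelation of the AR(1) component;
    ``drift_rel`` scales the slow cosine drift amplitude relative to the
    noise sd; the noise sd itself is derived from the target SNR.
    """

    ar_coef: float = 0.3
    drift_rel: float = 1.0
    drift_period_s: float = 300.0

    def __post_init__(self) -> None:
        if not (0 <= self.ar_coef < 1):
            raise ValueError("AR coefficient must be in [0, 1)")


@dataclass
class GroundTruth:
    """True generative model plus nuisance structure for simulation."""

    model: DCMModel
    hrf: HRFSpec = field(default_factory=HRFSpec)
    baseline: float = 0.0
    snr: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_jitter_sd: float = 0.05
    dt_s: float = 0.125

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be > 0")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "snr": self.snr, "baseline": self.baseline,
            "subject_jitter_sd": self.subject_jitter_sd, "dt_s": self.dt_s,
            "noise": vars(self.noise), "hrf": vars(self.hrf),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        self.model.to_json(str(path).replace(".json", "_model.json"))


def scenario_paper_effect(strength: float = 0.4, snr: float = 2.0,
                          subject_jitter_sd: float = 0.05) -> GroundTruth:
    """Preset ground truth mirroring the winning model's sign pattern.

    Driving phonetic input excites the four AC nodes; AC->PT forward
    coupling is excitatory, all PT->AC feedback is inhibitory (as is the
    left-to-right lateral homolog connection); the place-of-articulation
    modulator puts an inhibitory weight of ``-|strength|`` on the
    connection from the right lateral AC to PT, and nothing else.
    """
    nodes = DEFAULT_NODES
    mask = build_connectivity_mask(nodes)
    n = len(nodes)
    ix = {lab: i for i, lab in enumerate(nodes)}
    A = np.diag(np.full(n, -0.5))

    def setA(dst, src, w):
        assert mask.matrix[ix[dst], ix[src]]
        A[ix[dst], ix[src]] = w

    for hemi in "LR":  # within-hemisphere neighbours, excitatory
        setA(f"{hemi}_medial_AC", f"{hemi}_lateral_AC", 0.2)
        setA(f"{hemi}_lateral_AC", f"{hemi}_medial_AC", 0.2)
    setA("R_medial_AC", "L_medial_AC", 0.2)
    setA("L_medial_AC", "R_medial_AC", 0.2)
    setA("R_lateral_AC", "L_lateral_AC", -0.2)  # inhibited homolog link
    setA("L_lateral_AC", "R_lateral_AC", 0.2)
    for ac in ("L_medial_AC", "L_lateral_AC", "R_medial_AC", "R_lateral_AC"):
        setA("L_PT", ac, 0.25)       # forward AC -> PT
        setA(ac, "L_PT", -0.2)       # inhibitory PT feedback

    B = np.zeros((n, n))
    B[ix["L_PT"], ix["R_lateral_AC"]] = -abs(strength)
    mask_B = np.zeros((n, n), dtype=bool)
    mask_B[ix["L_PT"], ix["R_lateral_AC"]] = True

    C = np.zeros((n, 1))
    mask_C = np.zeros((n, 1), dtype=bool)
    for ac in ("L_medial_AC", "L_lateral_AC", "R_medial_AC", "R_lateral_AC"):
        C[ix[ac], 0] = 0.4
        mask_C[ix[ac], 0] = True

    model = DCMModel(nodes=nodes, A=A, B={"poa": B}, C=C,
                     mask_A=mask.matrix.copy(), mask_B={"poa": mask_B},
                     mask_C=mask_C)
    model.validate()
    return GroundTruth(model=model, snr=snr,
                       subject_jitter_sd=subject_jitter_sd)


def _jitter_model(model: DCMModel, sd: float, rng: np.ndarray,
                  inputs) -> DCMModel:
    """Gaussian jitter on unmasked A/B/C entries, truncated to stability."""
    if sd == 0:
        return model
    for _ in range(10):
        m = model.copy()
        m.A[m.mask_A] += rng.normal(0, sd, size=int(m.mask_A.sum()))
        for k in m.B:
            m.B[k][m.mask_B[k]] += rng.normal(0, sd, size=int(m.mask_B[k].sum()))
        m.C[m.mask_C] += rng.normal(0, sd, size=int(m.mask_C.sum()))
        if check_stability(m, inputs):
            return m
    raise RuntimeError("could not draw a stable jittered model in 10 tries")


def _ar1_noise(rng, shape: tuple[int, int], rho: float) -> np.ndarray:
    """AR(1)-filtered unit-variance Gaussian noise (stationary scaling)."""
    w = rng.standard_normal(shape)
    if rho == 0:
        return w
    out = np.empty_like(w)
    out[0] = w[0]
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + w[t]
    return out * np.sqrt(1 - rho ** 2)


def generate_subject(gt: GroundTruth, design: ExperimentalDesign,
                     seed: int) -> RoiTimeSeries:
    """One subject's ROI BOLD: jittered truth + drift + AR(1) noise at SNR."""
    rng = np.random.default_rng(seed)
    inputs = build_input_functions(design, dt_s=gt.dt_s)
    model = _jitter_model(gt.model, gt.subject_jitter_sd, rng, inputs)
    clean = forward_predict(model, inputs, hrf=gt.hrf, tr_s=design.tr_s)
    y = clean.values + gt.baseline
    V, n = y.shape
    sig_sd = clean.values.std(axis=0)
    noise_sd = sig_sd / gt.snr
    noise = _ar1_noise(rng, (V, n), gt.noise.ar_coef) * noise_sd
    t = np.arange(V) * design.tr_s
    phase = rng.uniform(0, 2 * np.pi, size=n)
    drift = (gt.noise.drift_rel * noise_sd
             * np.cos(2 * np.pi * t[:, None] / gt.noise.drift_period_s
                      + phase[None, :]))
    return RoiTimeSeries(values=y + noise + drift, nodes=model.nodes,
                         tr_s=design.tr_s,
                         volumes_per_run=clean.volumes_per_run,
                         unstable=clean.unstable)


@dataclass
class SyntheticDataset:
    """Per-subject designs and ROI series plus the generating ground truth."""

    designs: list[ExperimentalDesign]
    series: list[RoiTimeSeries]
    ground_truth: GroundTruth
    master_seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ground_truth.to_json(out / "ground_truth.json")
        (out / "dataset.json").write_text(json.dumps(
            {"n_subjects": self.n_subjects, "master_seed": self.master_seed},
            indent=1, sort_keys=True) + "\n")
        for s, (design, ts) in enumerate(zip(self.designs, self.series), 1):
            sub = out / f"sub-{s:02d}"
            sub.mkdir(exist_ok=True)
            design.to_events_tsv(sub / "events.tsv")
            ts.to_tsv(sub / "roi_timeseries.tsv", sub / "roi_timeseries.json")

    @classmethod
    def read(cls, out_dir: str | Path, ground_truth: GroundTruth,
             params: DesignParams) -> "SyntheticDataset":
        out = Path(out_dir)
        meta = json.loads((out / "dataset.json").read_text())
        designs, series = [], []
        for s in range(1, meta["n_subjects"] + 1):
            sub = out / f"sub-{s:02d}"
            designs.append(ExperimentalDesign.from_events_tsv(
                sub / "events.tsv", params))
            series.append(RoiTimeSeries.from_tsv(
                sub / "roi_timeseries.tsv", sub / "roi_timeseries.json"))
        return cls(designs, series, ground_truth, meta["master_seed"])


def generate_group(gt: GroundTruth, n_subjects: int = 10,
                   master_seed: int = 0,
                   design_overrides: Mapping[str, object] | None = None
                   ) -> SyntheticDataset:
    """Independent designs and noise per subject from one master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    designs, series = [], []
    for child in ss.spawn(n_subjects):
        d_seed, n_seed = (int(s) for s in child.generate_state(2))
        design = generate_design(d_seed, overrides=design_overrides)
        designs.append(design)
        series.append(generate_subject(gt, design, int(n_seed)))
    return SyntheticDataset(designs, series, gt, master_seed)
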