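"""End-to-end orchestration: simulate -> GLM/ANOVA -> DCM -> BMS -> BMA.

A single master seed fans out (via numpy seed sequences) to per-stage
seeds, so every stage is independently reproducible; every artifact
embeds the master seed and a hash of the canonical config dump.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import build_input_functions
from .dcm import RoiTimeSeries
from .glm import (build_design_matrix, extract_condition_responses, fit_glm,
                  group_contrast_test, posthoc_lsd, rm_anova)
from .invert import InversionSettings, invert_model
from .modelspace import (BMAResult, BMSResult, bma, bms,
                         build_connectivity_mask, enumerate_poa_models)
from .simulate import (GroundTruth, SyntheticDataset, generate_group,
                       scenario_paper_effect)

log = logging.getLogger("audconn")

CONFIG_VERSION = 1
SCENARIOS = {"paper_poa": scenario_paper_effect}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    master_seed: int = 0
    n_subjects: int = 10
    n_runs: int = 5
    scenario: str = "paper_poa"
    strength_hz: float = 0.4
    snr: float = 2.0
    subject_jitter_sd: float = 0.05
    bms_mode: str = "ffx"
    max_iter: int = 128
    tol_nats: float = 1e-4
    out_dir: str = "results/run"
    version: int = CONFIG_VERSION

    def validate(self) -> "PipelineConfig":
        if self.snr <= 0:
            raise ConfigError("snr must be > 0")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ConfigError("n_subjects and n_runs must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"known: {sorted(SCENARIOS)}")
        if self.bms_mode not in ("ffx", "rfx"):
            raise ConfigError("bms_mode must be 'ffx' or 'rfx'")
        if self.version != CONFIG_VERSION:
            raise ConfigError(f"config version {self.version} != {CONFIG_VERSION}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        doc = self.to_dict()
        doc.pop("out_dir")  # where results land is not part of the science
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse, default and schema-check a YAML/JSON/dict config."""
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)
    if doc is None:
        doc = {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc).validate()


def _stamp(doc: dict, config: PipelineConfig) -> dict:
    doc["config_hash"] = config.config_hash
    doc["master_seed"] = config.master_seed
    return doc


# ---------------------------------------------------------------------------
# reusable stages

def stage_simulate(config: PipelineConfig) -> SyntheticDataset:
    gt = SCENARIOS[config.scenario](strength=config.strength_hz,
                                    snr=config.snr,
                                    subject_jitter_sd=config.subject_jitter_sd)
    return generate_group(gt, n_subjects=config.n_subjects,
                          master_seed=config.master_seed,
                          design_overrides={"n_runs": config.n_runs})


def stage_glm(dataset: SyntheticDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-subject GLM betas and the stacked condition-cell array."""
    betas, cell_list = [], []
    for s, (design, ts) in enumerate(zip(dataset.designs, dataset.series), 1):
        X = build_design_matrix(design)
        fit = fit_glm(ts, X)
        b = fit.betas.loc[["phonetic", "poa", "vot", "inter"]].copy()
        b.insert(0, "subject", s)
        betas.append(b.reset_index(names="regressor"))
        cell_list.append(extract_condition_responses(fit))
    return pd.concat(betas, ignore_index=True), np.stack(cell_list)


def stage_dcm(dataset: SyntheticDataset, max_iter: int = 128,
              tol_nats: float = 1e-4):
    """Invert the 16-model PoA space for every subject.

    Returns (model space, log-evidence matrix subjects x models, fits).
    """
    space = enumerate_poa_models(
        build_connectivity_mask(dataset.ground_truth.model.nodes))
    settings = InversionSettings(max_iter=max_iter, tol_nats=tol_nats)
    lme = np.zeros((dataset.n_subjects, space.n_models))
    fits = []
    for s, (design, ts) in enumerate(zip(dataset.designs, dataset.series)):
        inputs = build_input_functions(design, dt_s=dataset.ground_truth.dt_s)
        row = []
        for m, member in enumerate(space.members):
            res = invert_model(ts, member, inputs, settings=settings,
                               hrf=dataset.ground_truth.hrf)
            lme[s, m] = res.free_energy
            row.append(res)
        fits.append(row)
        log.info("subject %d/%d inverted (%d models)", s + 1,
                 dataset.n_subjects, space.n_models)
    return space, lme, fits


def recovery_correlation(bma_result: BMAResult, gt: GroundTruth,
                         space) -> float:
    """Correlation between true and BMA-estimated unmasked parameters.

    Compares A off-diagonal entries over the connectivity mask, B over
    the union of the model space's modulated connections, and C over the
    input mask.
    """
    truth = gt.model
    mask_B_union = {m: np.zeros_like(truth.mask_A) for m in truth.modulators}
    for member in space.members:
        for m in member.modulators:
            mask_B_union[m] |= member.mask_B[m]
    true_vec = np.concatenate(
        [truth.A[truth.mask_A]]
        + [truth.B[m][mask_B_union[m]] for m in sorted(mask_B_union)]
        + [truth.C[truth.mask_C]])
    est_vec = bma_result.flatten(truth.mask_A, mask_B_union, truth.mask_C)
    return float(np.corrcoef(true_vec, est_vec)[0, 1])


def run_end_to_end(config: PipelineConfig) -> dict:
    """Full pipeline; writes all artifacts under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        config.dump(out / "config.yaml")

        t0 = time.perf_counter()
        dataset = stage_simulate(config)
        dataset.write(out / "dataset")
        timings["simulate"] = time.perf_counter() - t0
        log.info("simulate: %d subjects, seed %d, %.1fs", config.n_subjects,
                 config.master_seed, timings["simulate"])

        t0 = time.perf_counter()
        betas, cells = stage_glm(dataset)
        betas.to_csv(out / "betas.csv", index=False)
        anova = rm_anova(cells)
        anova.to_csv(out / "anova.csv", index=False)
        posthoc = posthoc_lsd(cells, factors=(0, 2),
                              level_names=[("L", "R"), None, ("alveolar",
                                                              "bilabial"),
                                           None])
        posthoc.to_csv(out / "posthoc.csv", index=False)
        poa_betas = (betas[betas.regressor == "poa"]
                     .drop(columns=["regressor", "subject"]).mean(axis=1))
        poa_test = group_contrast_test(poa_betas.to_numpy())
        timings["glm"] = time.perf_counter() - t0
        log.info("glm+anova: %.1fs", timings["glm"])

        t0 = time.perf_counter()
        space, lme, fits = stage_dcm(dataset, config.max_iter, config.tol_nats)
        pd.DataFrame(lme, columns=space.connection_labels()).to_csv(
            out / "evidence.csv", index=False)
        sel = bms(lme, mode=config.bms_mode, seed=config.master_seed)
        avg = bma(fits, sel)
        corr = recovery_correlation(avg, dataset.ground_truth, space)
        timings["dcm"] = time.perf_counter() - t0
        log.info("dcm+bms+bma: %.1fs", timings["dcm"])

        report = _stamp({
            "n_subjects": config.n_subjects,
            "bms_mode": sel.mode,
            "bms_winner": sel.winner,
            "bms_winner_connection": space.connection_labels()[sel.winner],
            "bms_pP": sel.pP.tolist(),
            "poa_group_t": poa_test.t,
            "poa_group_p": poa_test.p,
            "anova": anova.to_dict(orient="records"),
            "bma_A": avg.A.tolist(),
            "bma_B": {k: v.tolist() for k, v in avg.B.items()},
            "bma_C": avg.C.tolist(),
            "recovery_correlation": corr,
        }, config)
        (out / "bms.json").write_text(json.dumps(_stamp(
            {"mode": sel.mode, "pP": sel.pP.tolist(), "winner": sel.winner},
            config), indent=1, sort_keys=True) + "\n")
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
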