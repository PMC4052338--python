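"""Seeded validation experiments: parameter recovery, model recovery, power.

These are the package's self-checks on synthetic data with known ground
truth: they quantify whether the full estimation pipeline can recover the
parameters and the modulated connection it is supposed to find, and
whether the factorial ANOVA detects a left-lateralized place-of-
articulation effect at realistic sample sizes.  Problem sizes default to
2 runs per subject, a scaled-down acquisition that keeps the experiments
quick while preserving the block structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import build_input_functions, generate_design
from .dcm import RoiTimeSeries
from .glm import build_design_matrix, extract_condition_responses, fit_glm, rm_anova
from .invert import InversionSettings, invert_model
from .modelspace import bms, bma, build_connectivity_mask, enumerate_poa_models
from .pipeline import recovery_correlation, stage_dcm
from .simulate import generate_group, scenario_paper_effect

TRUE_CONNECTION = "R_lateral_AC->L_PT"


@dataclass
class RecoveryResult:
    correlation: float
    winner: int
    winner_connection: str
    true_connection: str = TRUE_CONNECTION

    @property
    def winner_correct(self) -> bool:
        return self.winner_connection == self.true_connection


def parameter_recovery(n_subjects: int = 10, n_runs: int = 2,
                       strength: float = 0.4, snr: float = 2.0,
                       master_seed: int = 0) -> RecoveryResult:
    """Group BMA parameter recovery under the winning-model scenario.

    Simulates a group from the preset ground truth, inverts all 16 models
    per subject, selects by fixed-effects BMS, averages by BMA, and
    correlates the averaged A/B/C parameters with the generating values.
    """
    gt = scenario_paper_effect(strength, snr=snr)
    ds = generate_group(gt, n_subjects=n_subjects, master_seed=master_seed,
                        design_overrides={"n_runs": n_runs})
    space, lme, fits = stage_dcm(ds)
    sel = bms(lme, mode="ffx")
    avg = bma(fits, sel)
    corr = recovery_correlation(avg, gt, space)
    return RecoveryResult(correlation=corr, winner=sel.winner,
                          winner_connection=space.connection_labels()[sel.winner])


def model_recovery(n_replicates: int = 10, n_subjects: int = 10,
                   n_runs: int = 2, strength: float = 0.4, snr: float = 2.0,
                   base_seed: int = 1000,
                   settings: InversionSettings | None = None
                   ) -> list[RecoveryResult]:
    """Repeated model-recovery experiments: does the true model win BMS?

    Each replicate simulates an independent group (master seed
    ``base_seed + r``), inverts the 16-model space for every subject and
    records the fixed-effects BMS winner.  Memory-light: only the
    evidence matrix is kept per replicate.
    """
    settings = settings or InversionSettings()
    gt = scenario_paper_effect(strength, snr=snr)
    space = enumerate_poa_models(build_connectivity_mask(gt.model.nodes))
    labels = space.connection_labels()
    out = []
    for r in range(n_replicates):
        ds = generate_group(gt, n_subjects=n_subjects,
                            master_seed=base_seed + r,
                            design_overrides={"n_runs": n_runs})
        lme = np.zeros((n_subjects, space.n_models))
        for s, (design, ts) in enumerate(zip(ds.designs, ds.series)):
            inputs = build_input_functions(design, dt_s=gt.dt_s)
            for m, member in enumerate(space.members):
                lme[s, m] = invert_model(ts, member, inputs,
                                         settings=settings,
                                         hrf=gt.hrf).free_energy
        sel = bms(lme, mode="ffx")
        out.append(RecoveryResult(correlation=np.nan, winner=sel.winner,
                                  winner_connection=labels[sel.winner]))
    return out


@dataclass
class PowerResult:
    n_replicates: int
    rate_poa: float
    rate_poa_by_hemisphere: float
    rate_vot_null: float
    rate_hemisphere_null: float


def simulate_glm_subject(design, rng, effects: dict[str, np.ndarray],
                         noise_sd: float = 1.0) -> RoiTimeSeries:
    """ROI series with known regressor effects plus white noise.

    ``effects`` maps regressor name -> per-node amplitudes (5 nodes in
    default order); everything else in the design matrix has beta 0.
    """
    X = build_design_matrix(design)
    beta = np.zeros((X.X.shape[1], 5))
    for name, amps in effects.items():
        beta[X.names.index(name)] = amps
    y = X.X @ beta + noise_sd * rng.standard_normal((X.n_volumes, 5))
    from .dcm import DEFAULT_NODES
    p = design.params
    return RoiTimeSeries(y, DEFAULT_NODES, p.tr_s,
                         (p.volumes_per_run,) * p.n_runs)


def anova_power(n_replicates: int = 20, n_subjects: int = 10,
                n_runs: int = 2, base_seed: int = 500,
                poa_left: float = 0.5, poa_right: float = 0.1,
                between_sd: float = 0.15, noise_sd: float = 1.0,
                alpha: float = 0.05) -> PowerResult:
    """Detection rates for a left-lateralized alveolar (PoA) effect.

    Subjects carry a PoA modulator effect of ``poa_left`` in the two left
    AC nodes and ``poa_right`` in the right ones (plus between-subject
    variation), with VOT and hemisphere effects simulated null; rates are
    the fraction of replicates in which each ANOVA effect is significant.
    Nodes order: L-medial, L-lateral, L-PT, R-medial, R-lateral.
    """
    hits = {"PoA": 0, "PoAxH": 0, "VOT": 0, "H": 0}
    for r in range(n_replicates):
        rng = np.random.default_rng(base_seed + r)
        cells = []
        for s in range(n_subjects):
            design = generate_design(int(rng.integers(2 ** 31)),
                                     n_runs=n_runs)
            poa_amp = np.array([poa_left, poa_left, 0.0,
                                poa_right, poa_right])
            poa_amp += between_sd * rng.standard_normal(5)
            effects = {
                "phonetic": np.full(5, 2.0)
                + between_sd * rng.standard_normal(5),
                "poa": poa_amp,
            }
            ts = simulate_glm_subject(design, rng, effects, noise_sd)
            fit = fit_glm(ts, build_design_matrix(design))
            cells.append(extract_condition_responses(fit))
        tab = rm_anova(np.stack(cells)).set_index("effect")
        hits["PoA"] += tab.loc["PoA", "p_gg"] < alpha
        hits["PoAxH"] += tab.loc["Hemisphere x PoA", "p_gg"] < alpha
        hits["VOT"] += tab.loc["VOT", "p_gg"] < alpha
        hits["H"] += tab.loc["Hemisphere", "p_gg"] < alpha
    n = n_replicates
    return PowerResult(n, hits["PoA"] / n, hits["PoAxH"] / n,
                       hits["VOT"] / n, hits["H"] / n)
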