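"""Experimental design for the CV-syllable block paradigm.

The study presents consonant-vowel (CV) syllables in a block design: per
run, 3 ON blocks for each cell of place-of-articulation (PoA: alveolar vs
bilabial) x voice-onset time (VOT: short vs long), 10 trials of 700 ms per
20-s block, interleaved with 16-s silent OFF blocks.  One trial per block
is a monaural target trial (10% of trials) that is excluded from the
analyses of interest.

`generate_design` builds the seeded trial timetable; `build_input_functions`
samples it onto a micro-time grid as the driving "phonetic input" (all
non-target trials, irrespective of PoA/VOT) plus mean-centred parametric
modulators for PoA, VOT and their interaction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POA_LEVELS = ("alveolar", "bilabial")
VOT_LEVELS = ("short", "long")
#: initial consonant implied by the PoA x VOT cell
CONSONANT = {
    ("alveolar", "short"): "d",
    ("alveolar", "long"): "t",
    ("bilabial", "short"): "b",
    ("bilabial", "long"): "p",
}

EVENT_COLUMNS = (
    "onset", "duration", "trial_type", "poa", "vot",
    "voice", "vowel", "is_target", "run",
)


class DesignError(ValueError):
    """Raised when design parameters are inconsistent."""


@dataclass(frozen=True)
class DesignParams:
    """Timing/layout parameters of the block design (seconds)."""

    n_runs: int = 5
    volumes_per_run: int = 220
    tr_s: float = 2.0
    block_s: float = 20.0
    off_s: float = 16.0
    trial_s: float = 0.7
    trials_per_block: int = 10
    blocks_per_cell: int = 3
    n_voices: int = 8
    vowels: tuple[str, ...] = ("a", "o")

    @property
    def blocks_per_run(self) -> int:
        return self.blocks_per_cell * len(POA_LEVELS) * len(VOT_LEVELS)

    @property
    def run_length_s(self) -> float:
        return self.volumes_per_run * self.tr_s

    def validate(self) -> None:
        if self.n_runs < 1:
            raise DesignError("n_runs must be >= 1")
        if self.trials_per_block * self.trial_s > self.block_s + 1e-12:
            raise DesignError(
                f"block_s={self.block_s} cannot hold "
                f"{self.trials_per_block} trials of {self.trial_s} s"
            )
        span = self.blocks_per_run * (self.block_s + self.off_s)
        if span > self.run_length_s + 1e-12:
            raise DesignError(
                f"ON+OFF span {span} s exceeds run length {self.run_length_s} s "
                f"({self.volumes_per_run} volumes x {self.tr_s} s)"
            )


@dataclass
class ExperimentalDesign:
    """Trial timetable plus acquisition geometry.

    ``trials`` has one row per stimulus with columns ``run`` (1-based),
    ``onset`` (seconds, run-relative, half-open [onset, onset+duration)),
    ``duration``, ``poa``, ``vot``, ``voice`` (1..8), ``vowel``,
    ``is_target``.
    """

    trials: pd.DataFrame
    params: DesignParams

    @property
    def n_runs(self) -> int:
        return self.params.n_runs

    @property
    def tr_s(self) -> float:
        return self.params.tr_s

    @property
    def run_length_volumes(self) -> int:
        return self.params.volumes_per_run

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_targets(self) -> int:
        return int(self.trials["is_target"].sum())

    def subset_runs(self, runs: Sequence[int]) -> "ExperimentalDesign":
        """Design restricted to the given runs, renumbered 1..len(runs)."""
        runs = list(runs)
        sub = self.trials[self.trials["run"].isin(runs)].copy()
        sub["run"] = sub["run"].map({r: i + 1 for i, r in enumerate(runs)})
        params = replace(self.params, n_runs=len(runs))
        return ExperimentalDesign(sub.reset_index(drop=True), params)

    # -- BIDS-style events I/O -------------------------------------------
    def to_events_tsv(self, path: str | Path) -> None:
        df = self.trials.copy()
        df["trial_type"] = np.where(df["is_target"], "target", "syllable")
        df["is_target"] = df["is_target"].astype(int)
        df[list(EVENT_COLUMNS)].to_csv(
            path, sep="\t", index=False, float_format="%.6f", lineterminator="\n"
        )

    @classmethod
    def from_events_tsv(cls, path: str | Path, params: DesignParams) -> "ExperimentalDesign":
        df = pd.read_csv(path, sep="\t")
        df["is_target"] = df["is_target"].astype(bool)
        df = df.drop(columns=["trial_type"])
        return cls(df, params)


def generate_design(seed: int, n_runs: int | None = None,
                    overrides: Mapping[str, object] | None = None) -> ExperimentalDesign:
    """Generate a seeded realization of the block design.

    Block order within each run is a seeded random permutation of the 12
    ON blocks (3 per PoA x VOT cell).  Within a block the 13 s of slack
    around the 10 x 0.7 s stimuli is split into per-trial silent gaps by a
    seeded flat Dirichlet draw, so the 10 trials together span exactly the
    block duration.  One trial per block is chosen uniformly as the
    monaural target trial.
    """
    kw = dict(overrides or {})
    if n_runs is not None:
        kw["n_runs"] = n_runs
    try:
        params = replace(DesignParams(), **kw)
    except TypeError as exc:
        raise DesignError(f"unknown design parameter: {exc}") from exc
    params.validate()

    rng = np.random.default_rng(seed)
    cells = [(p, v) for p in POA_LEVELS for v in VOT_LEVELS]
    rows = []
    for run in range(1, params.n_runs + 1):
        order = rng.permutation(params.blocks_per_cell * len(cells))
        t = 0.0
        for b in order:
            poa, vot = cells[b % len(cells)]
            slack = params.block_s - params.trials_per_block * params.trial_s
            gaps = rng.dirichlet(np.ones(params.trials_per_block)) * slack
            target = rng.integers(params.trials_per_block)
            onset = t
            for i in range(params.trials_per_block):
                rows.append({
                    "run": run,
                    "onset": onset,
                    "duration": params.trial_s,
                    "poa": poa,
                    "vot": vot,
                    "voice": int(rng.integers(1, params.n_voices + 1)),
                    "vowel": params.vowels[rng.integers(len(params.vowels))],
                    "is_target": i == target,
                })
                onset += params.trial_s + gaps[i]
            t += params.block_s + params.off_s
    trials = pd.DataFrame(rows)
    return ExperimentalDesign(trials, params)


# ---------------------------------------------------------------------------
# input functions

@dataclass(frozen=True)
class ModulatorCoding:
    """+-1 condition codes assigned to the modulator levels."""

    poa: Mapping[str, float] = field(
        default_factory=lambda: {"alveolar": 1.0, "bilabial": -1.0})
    vot: Mapping[str, float] = field(
        default_factory=lambda: {"long": 1.0, "short": -1.0})


@dataclass
class InputFunctions:
    """Sampled stimulus functions on the micro-time grid.

    ``u_phonetic`` is the boxcar of all non-target stimulus presentations
    (the driving input); ``u_poa``, ``u_vot``, ``u_inter`` are the
    parametric modulators, mean-centred over the nonzero support of
    ``u_phonetic``; ``u_target`` flags target-trial presentations (a
    nuisance signal, never part of ``u_phonetic``).
    """

    dt_s: float
    samples_per_run: int
    n_runs: int
    u_phonetic: np.ndarray
    u_poa: np.ndarray
    u_vot: np.ndarray
    u_inter: np.ndarray
    u_target: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.u_phonetic.shape[0]

    def stack(self, names: Sequence[str]) -> np.ndarray:
        """(n_samples, len(names)) array of the named signals."""
        lut = {
            "phonetic": self.u_phonetic, "poa": self.u_poa, "vot": self.u_vot,
            "inter": self.u_inter, "target": self.u_target,
        }
        return np.column_stack([lut[n] for n in names])

    def run_slices(self) -> list[slice]:
        return [slice(r * self.samples_per_run, (r + 1) * self.samples_per_run)
                for r in range(self.n_runs)]


def build_input_functions(design: ExperimentalDesign, dt_s: float = 0.125,
                          coding: ModulatorCoding | None = None) -> InputFunctions:
    """Sample the design onto a micro-time grid.

    A sample at time ``k*dt_s`` is inside a trial iff it falls in
    ``[onset, onset+duration)``; runs are concatenated back to back.
    ``dt_s`` must divide the TR so the volume grid is a subset of the
    micro grid.
    """
    coding = coding or ModulatorCoding()
    p = design.params
    ratio = p.tr_s / dt_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise DesignError(f"dt_s={dt_s} does not divide tr_s={p.tr_s}")
    spr = int(round(p.run_length_s / dt_s))
    n = spr * p.n_runs

    u_phon = np.zeros(n)
    u_targ = np.zeros(n)
    raw_poa = np.zeros(n)
    raw_vot = np.zeros(n)

    for row in design.trials.itertuples(index=False):
        off = (row.run - 1) * spr
        i0 = off + int(np.ceil(row.onset / dt_s - 1e-9))
        i1 = off + int(np.ceil((row.onset + row.duration) / dt_s - 1e-9))
        i1 = min(i1, n)
        if row.is_target:
            u_targ[i0:i1] = 1.0
        else:
            u_phon[i0:i1] = 1.0
            raw_poa[i0:i1] = coding.poa[row.poa]
            raw_vot[i0:i1] = coding.vot[row.vot]

    support = u_phon > 0

    def center(raw: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        if support.any():
            out[support] = raw[support] - raw[support].mean()
        return out

    raw_inter = raw_poa * raw_vot
    return InputFunctions(
        dt_s=dt_s, samples_per_run=spr, n_runs=p.n_runs,
        u_phonetic=u_phon, u_poa=center(raw_poa), u_vot=center(raw_vot),
        u_inter=center(raw_inter), u_target=u_targ,
    )
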