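"""Synthetic time-lapse growth curves and serial competition-assay records.

The generator emulates the experimental designs the inference pipeline
consumes: fluorescence time-lapse of one labeled subclone (homotypic or
heterotypic seeding), and serial co-culture rounds in which cells are grown
for 72 or 96 h, the labeled-type proportion is measured by flow cytometry at
seeding and at harvest, and the culture is replated at the original density
with the harvested composition.

Observation noise is multiplicative (lognormal) on the fluorescence proxy —
intensities are positive and the analysis works in log space — and
flow-cytometry proportions are binomial counts out of ``cytometry_n`` events.
Round 1 of a serial assay can be made extra-dispersed (``first_round_inflation``)
to emulate the longer, more stressful set-up of the initial seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import LVParams, PhaseSchedule, simulate

__all__ = [
    "NoiseConfig",
    "ExperimentDesign",
    "GrowthCurve",
    "CompetitionAssayRecord",
    "generate_homotypic_timelapse",
    "generate_heterotypic_timelapse",
    "generate_competition_assays",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise settings.

    ``intensity_sd`` is the standard deviation of additive normal noise on
    the log fluorescence proxy.  ``cytometry_n`` is the number of events per
    flow-cytometry measurement; ``None`` is the infinite-count sentinel
    (measured proportion equals the true proportion).  ``first_round_inflation``
    multiplies the sampling standard deviation of round-1 proportion
    measurements (implemented by shrinking the effective event count by the
    square of the factor).
    """

    seed: int = 0
    intensity_sd: float = 0.05
    cytometry_n: Optional[int] = 10_000
    first_round_inflation: float = 3.0

    def __post_init__(self) -> None:
        if self.intensity_sd < 0:
            raise ValueError("intensity_sd must be >= 0")
        if self.cytometry_n is not None and self.cytometry_n < 1:
            raise ValueError("cytometry_n must be >= 1 (or None for exact)")
        if self.first_round_inflation < 1:
            raise ValueError("first_round_inflation must be >= 1")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseConfig":
        return cls(seed=seed, intensity_sd=0.0, cytometry_n=None, first_round_inflation=1.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a synthetic experiment.

    The default winner-proportion grid spans the wide range of seeding
    ratios used in the serial competition assays; frames are 45 min apart
    (``frame_interval = 0.75`` h).
    """

    w0_grid: tuple = (0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95)
    n_rounds: int = 3
    round_duration: float = 72.0
    frame_interval: float = 0.75
    frame_start: float = 0.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(not (0.0 < w < 1.0) for w in self.w0_grid):
            raise ValueError("w0_grid values must lie strictly in (0, 1)")
        if self.n_rounds < 1 or self.replicates < 1:
            raise ValueError("n_rounds and replicates must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def frame_times(self) -> np.ndarray:
        n = int(math.floor((self.round_duration - self.frame_start) / self.frame_interval + 1e-9))
        return self.frame_start + self.frame_interval * np.arange(n + 1)


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's time series of a labeled type's population proxy."""

    condition: str  # "homotypic" | "heterotypic"
    labeled_type: str  # "L" | "W"
    replicate: str
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in ("homotypic", "heterotypic"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.labeled_type not in ("L", "W"):
            raise ValueError(f"labeled_type must be 'L' or 'W', got {self.labeled_type!r}")
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.signal, dtype=float)
        if len(t) != len(x):
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(x <= 0):
            raise ValueError("signals must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", x)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "condition": self.condition,
                "labeled_type": self.labeled_type,
                "replicate": self.replicate,
                "time_h": self.times,
                "signal": self.signal,
            }
        )


@dataclass(frozen=True)
class CompetitionAssayRecord:
    """One serial-assay round: measured winner proportions at seeding and harvest."""

    round_index: int
    duration_h: float
    w_start: float
    w_end: float
    replicate: str

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        for name in ("w_start", "w_end"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def degenerate(self) -> bool:
        """True when a measured proportion hit 0 or 1 (logit undefined)."""
        return self.w_start in (0.0, 1.0) or self.w_end in (0.0, 1.0)


def _observe(true_sizes: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return true_sizes.copy()
    return np.exp(np.log(true_sizes) + rng.normal(0.0, sd, size=len(true_sizes)))


def _homotypic_trajectory(
    params: LVParams, schedule: PhaseSchedule, which: str, times: np.ndarray
) -> np.ndarray:
    initial = (1.0, 0.0) if which == "L" else (0.0, 1.0)
    tr = simulate(params, schedule, initial, times)
    return tr.L if which == "L" else tr.W


def generate_homotypic_timelapse(
    params: LVParams,
    schedule: PhaseSchedule,
    which: str,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseConfig = NoiseConfig(),
) -> list[GrowthCurve]:
    """Replicated homotypic time-lapse curves of one type seeded at size 1.

    The loser's homotypic curve follows the phase-2 model beyond ``t2`` (the
    phase-3 rate change applies to the winner only).
    """
    if which not in ("L", "W"):
        raise ValueError("which must be 'L' or 'W'")
    times = design.frame_times()
    if times[-1] > schedule.t_end:
        raise ValueError("round_duration exceeds schedule t_end")
    true = _homotypic_trajectory(params, schedule, which, times)
    rng = np.random.default_rng(noise.seed)
    return [
        GrowthCurve(
            condition="homotypic",
            labeled_type=which,
            replicate=f"{which}{i + 1}",
            times=times,
            signal=_observe(true, noise.intensity_sd, rng),
        )
        for i in range(design.replicates)
    ]


def generate_heterotypic_timelapse(
    params: LVParams,
    schedule: PhaseSchedule,
    labeled: str,
    w0: float,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseConfig = NoiseConfig(),
) -> list[GrowthCurve]:
    """Replicated curves of the labeled type from a mixed seeding at winner proportion w0."""
    if labeled not in ("L", "W"):
        raise ValueError("labeled must be 'L' or 'W'")
    if not (0.0 < w0 < 1.0):
        raise ValueError("w0 must lie strictly in (0, 1)")
    times = design.frame_times()
    tr = simulate(params, schedule, (1.0 - w0, w0), times)
    true = tr.L if labeled == "L" else tr.W
    rng = np.random.default_rng(noise.seed)
    return [
        GrowthCurve(
            condition="heterotypic",
            labeled_type=labeled,
            replicate=f"{labeled}w{w0:g}-{i + 1}",
            times=times,
            signal=_observe(true, noise.intensity_sd, rng),
        )
        for i in range(design.replicates)
    ]


def _sample_proportion(
    w: float, round_index: int, noise: NoiseConfig, rng: np.random.Generator
) -> float:
    if noise.cytometry_n is None:
        return w
    n = noise.cytometry_n
    if round_index == 1 and noise.first_round_inflation > 1.0:
        # inflate the sampling SD by the factor: effective count / factor^2
        n = max(1, round(n / noise.first_round_inflation**2))
    return rng.binomial(n, w) / n


def generate_competition_assays(
    params: LVParams,
    schedule: PhaseSchedule,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseConfig = NoiseConfig(),
) -> list[CompetitionAssayRecord]:
    """Serial competition-assay records over the design's seeding grid.

    Each round simulates one culture from total normalized size 1 at the
    current true winner proportion, records flow-cytometry measurements of
    the initial and final proportions, then replates: the total size resets
    to 1 while the true composition is preserved.  Measured proportions that
    hit exactly 0 or 1 are retained (the record's ``degenerate`` flag is set;
    downstream logit-based stages skip them).
    """
    dur = design.round_duration
    if dur < schedule.t2:
        raise ValueError("round_duration must be at least t2 (cover phase 2)")
    if dur > schedule.t_end:
        raise ValueError("round_duration exceeds schedule t_end")
    rng = np.random.default_rng(noise.seed)
    records: list[CompetitionAssayRecord] = []
    for w0 in design.w0_grid:
        for rep in range(1, design.replicates + 1):
            w = float(w0)
            rep_id = f"w{w0:g}-{rep}"
            for k in range(1, design.n_rounds + 1):
                meas_start = _sample_proportion(w, k, noise, rng)
                tr = simulate(params, schedule, (1.0 - w, w), [dur])
                w_end_true = float(tr.W[0] / (tr.L[0] + tr.W[0]))
                meas_end = _sample_proportion(w_end_true, k, noise, rng)
                records.append(
                    CompetitionAssayRecord(
                        round_index=k,
                        duration_h=dur,
                        w_start=meas_start,
                        w_end=meas_end,
                        replicate=rep_id,
                    )
                )
                w = w_end_true  # replate preserves the true composition
    return records
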