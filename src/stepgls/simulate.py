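"""Synthetic single-molecule trajectories: step function plus AR or
Gaussian noise.

The canonical fixture emulates a simulated RNA-unwinding trace: 33 steps at
2.5 kHz sampling, mostly upward unit steps occasionally interrupted by
downward ones, dwell times of 0.1-2.25 s except for six transient dwells of
31/18/18/80/80/84 ms following steps 1, 6, 7, 29, 30 and 31.  The noise is
an AR(7) process with coefficients 0.222, 0.072, 0.035, 0.015, 0.016, 0.003,
0.013, values typical of optical-tweezers unwinding data.

Free conventions of the fixture (the source analysis does not print them):
unit step magnitude, downward steps at positions 12, 20 and 27, and a noise
amplitude of 0.30 step units (stationary marginal SD).  Quantitative
comparisons against reference summary tables are therefore within sampling
error, not exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as _evaluate
from .autocorr import ARModel, simulate_ar, stationary_sd
from .config import RunConfig
from .io import Trace
from .stepfit import StepModel, detect_steps

__all__ = [
    "StepSpec",
    "AR7_COEFFICIENTS",
    "DEFAULT_FIXTURE_SEED",
    "ar7_noise",
    "unwinding_fixture",
    "render_trace",
    "replicate_study",
    "StudyResult",
]

#: AR(7) noise coefficients typical of optical-tweezers unwinding traces.
AR7_COEFFICIENTS = (0.222, 0.072, 0.035, 0.015, 0.016, 0.003, 0.013)

#: Dedicated seed for the fixture's random dwell times, so one study shares
#: a single step function while the noise varies from replicate to replicate.
DEFAULT_FIXTURE_SEED = 997

# (step number, dwell seconds) for the transient dwells following these steps
_TRANSIENT_DWELLS = ((1, 0.031), (6, 0.018), (7, 0.018),
                     (29, 0.080), (30, 0.080), (31, 0.084))
_DOWN_STEPS = (12, 20, 27)  # 1-based positions of the three downward steps
_N_STEPS = 33
_RATE = 2500.0
_DWELL_RANGE = (0.1, 2.25)


def ar7_noise(marginal_sd: float = 0.30) -> ARModel:
    """The canonical AR(7) noise model, scaled so its stationary marginal
    SD equals ``marginal_sd`` (default 0.30 step units)."""
    unit = ARModel(order=7, coefficients=AR7_COEFFICIENTS, innovation_sd=1.0)
    return ARModel(
        order=7,
        coefficients=AR7_COEFFICIENTS,
        innovation_sd=marginal_sd / stationary_sd(unit),
    )


@dataclass(frozen=True)
class StepSpec:
    """A step function in physical time: k+1 dwell durations (s), k signed
    step sizes (signal units), a baseline and a sampling rate (Hz)."""

    dwell_times: tuple[float, ...]
    step_sizes: tuple[float, ...]
    baseline: float = 0.0
    sampling_rate: float = _RATE

    def __post_init__(self) -> None:
        if len(self.dwell_times) != len(self.step_sizes) + 1:
            raise ValueError("need exactly one more dwell than steps")
        if any(d <= 0 for d in self.dwell_times):
            raise ValueError("dwell times must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def k(self) -> int:
        return len(self.step_sizes)

    def dwell_samples(self) -> np.ndarray:
        counts = np.rint(
            np.asarray(self.dwell_times) * self.sampling_rate
        ).astype(int)
        if np.any(counts < 1):
            short = np.flatnonzero(counts < 1).tolist()
            raise ValueError(
                f"dwell(s) {short} shorter than one sample at "
                f"{self.sampling_rate} Hz"
            )
        return counts

    def to_model(self) -> StepModel:
        counts = self.dwell_samples()
        return StepModel(
            baseline=self.baseline,
            step_indices=np.cumsum(counts[:-1]),
            step_sizes=np.asarray(self.step_sizes, dtype=float),
            n=int(counts.sum()),
            dt=1.0 / self.sampling_rate,
        )


def unwinding_fixture(seed: int = DEFAULT_FIXTURE_SEED) -> StepSpec:
    """The canonical 33-step unwinding step function.

    Dwells following steps 1, 6, 7, 29, 30 and 31 are fixed at 31, 18, 18,
    80, 80 and 84 ms; every other dwell (including the initial one) is drawn
    uniformly on [0.1, 2.25] s from ``seed``.  Steps are +1 unit except for
    downward -1 steps at positions 12, 20 and 27.
    """
    rng = np.random.default_rng(seed)
    dwells = rng.uniform(*_DWELL_RANGE, size=_N_STEPS + 1)
    for step_no, seconds in _TRANSIENT_DWELLS:
        dwells[step_no] = seconds  # dwell j follows step j (dwell 0 precedes)
    sizes = np.ones(_N_STEPS)
    sizes[np.asarray(_DOWN_STEPS) - 1] = -1.0
    return StepSpec(
        dwell_times=tuple(dwells),
        step_sizes=tuple(sizes),
        baseline=0.0,
        sampling_rate=_RATE,
    )


def render_trace(
    spec: StepSpec, noise: ARModel | None, seed=None
) -> tuple[Trace, StepModel]:
    """Sample the step function and add noise.

    Returns the noisy trace and the ground-truth StepModel in sample
    coordinates.  ``noise=None`` gives the pure step function.
    """
    truth = spec.to_model()
    values = truth.mean()
    if noise is not None:
        values = values + simulate_ar(noise, truth.n, seed)
    trace = Trace(values=values, dt=truth.dt)
    return trace, truth


@dataclass(frozen=True)
class StudyResult:
    """Replicate-level outcomes of a simulation study."""

    truth: StepModel
    table: pd.DataFrame
    reports: tuple[_evaluate.MatchReport, ...]

    def efficiency(self) -> pd.Series:
        return _evaluate.aggregate_efficiency(self.reports, self.truth)


def replicate_study(
    n_reps: int,
    config: RunConfig | None = None,
    seed: int = 0,
    noise: ARModel | None | str = "default",
    spec: StepSpec | None = None,
    fixture_seed: int = DEFAULT_FIXTURE_SEED,
) -> StudyResult:
    """Re-run detection on ``n_reps`` independent noise realizations of one
    shared step function.

    The step function is the canonical fixture (or ``spec``); only the noise
    is redrawn per replicate, with independent child seeds spawned from
    ``seed``.  ``noise`` defaults to the canonical AR(7) model at marginal SD
    0.30; pass ``None`` for noiseless traces or any ``ARModel`` (e.g. an
    order-0 model for Gaussian white noise).  Returns per-replicate
    detected/true step counts, false-positive and missed-step counts, plus
    the full match reports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or RunConfig()
    if spec is None:
        spec = unwinding_fixture(fixture_seed)
    if isinstance(noise, str):
        if noise != "default":
            raise ValueError("noise must be an ARModel, None or 'default'")
        noise = ar7_noise()
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    reports = []
    truth = spec.to_model()
    for rep, child in enumerate(children):
        trace, _ = render_trace(spec, noise, seed=child)
        fit = detect_steps(trace, config)
        report = _evaluate.match_steps(truth, fit.model)
        reports.append(report)
        rows.append(
            {
                "rep": rep,
                "n_detected": fit.model.k,
                "n_true": truth.k,
                "false_positives": len(report.false_positives),
                "missed_steps": len(report.missed_steps),
                "bic": fit.bic,
                "noise_order": fit.noise.order,
            }
        )
    return StudyResult(
        truth=truth, table=pd.DataFrame(rows), reports=tuple(reports)
    )
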