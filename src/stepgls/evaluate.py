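"""Scoring detected steps against a known step function.

Detected steps are matched to true steps greedily in increasing distance;
a pair is accepted only if the distance is at most half of the shorter dwell
adjacent to the true step, which keeps a detection from being credited to a
step on the far side of a dwell.  Unmatched detections are false positives;
unmatched true steps are missed steps.  (Historical output nomenclature
calls the latter "true negatives"; the standard term is false negatives.)

Location accuracy is reported as a signed percentage of the adjacent dwell:
a detection 10 samples left of a step whose left dwell is 50 samples long
deviates by -20%; 30 samples right with a 100-sample right dwell is +30%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepfit import StepModel

__all__ = [
    "MatchReport",
    "match_steps",
    "deviation_percent",
    "aggregate_efficiency",
    "summarize_counts",
]


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching one detected step set against the truth."""

    matched_pairs: tuple[tuple[int, int], ...]  # (true index, detected index)
    false_positives: tuple[int, ...]  # detected, no true partner
    missed_steps: tuple[int, ...]  # true, undetected ("true negatives")
    deviations_pct: tuple[float, ...]  # one per matched pair

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"true_index": t, "detected_index": d, "deviation_pct": dev,
             "kind": "match"}
            for (t, d), dev in zip(self.matched_pairs, self.deviations_pct)
        ]
        rows += [
            {"true_index": None, "detected_index": d, "deviation_pct": None,
             "kind": "false_positive"}
            for d in self.false_positives
        ]
        rows += [
            {"true_index": t, "detected_index": None, "deviation_pct": None,
             "kind": "missed_step"}
            for t in self.missed_steps
        ]
        return pd.DataFrame(
            rows,
            columns=["true_index", "detected_index", "deviation_pct", "kind"],
        )


def deviation_percent(
    true_index: int, detected_index: int, left_dwell: int, right_dwell: int
) -> float:
    """Signed step-location deviation as % of the adjacent true dwell.

    Negative (normalized by the left dwell) when the detection is early,
    positive (normalized by the right dwell) when late, 0 when exact.
    """
    if left_dwell <= 0 or right_dwell <= 0:
        raise ValueError("dwell lengths must be positive")
    delta = detected_index - true_index
    if delta == 0:
        return 0.0
    dwell = left_dwell if delta < 0 else right_dwell
    return 100.0 * delta / dwell


def match_steps(
    truth: StepModel, detected: StepModel, radius_scale: float = 1.0
) -> MatchReport:
    """Greedy nearest-neighbor matching of detected to true steps.

    Candidate pairs are visited in ascending |distance| (ties toward the
    earlier true step); a pair is accepted when both partners are unused and
    the distance is <= 50% of the shorter dwell adjacent to the true step
    (optionally shrunk by ``radius_scale``).
    """
    if truth.n != detected.n:
        raise ValueError("truth and detected models are on different lengths")
    t_idx = truth.step_indices
    d_idx = detected.step_indices
    dwells = truth.dwell_samples()
    # per true step: half the shorter adjacent dwell
    radius = radius_scale * 0.5 * np.minimum(dwells[:-1], dwells[1:])

    pairs = []
    for ti, t in enumerate(t_idx):
        for di, d in enumerate(d_idx):
            dist = abs(int(d) - int(t))
            if dist <= radius[ti]:
                pairs.append((dist, ti, di))
    pairs.sort()

    used_t: set[int] = set()
    used_d: set[int] = set()
    matched: list[tuple[int, int]] = []
    devs: list[float] = []
    for dist, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched.append((int(t_idx[ti]), int(d_idx[di])))
        devs.append(
            deviation_percent(
                int(t_idx[ti]), int(d_idx[di]),
                int(dwells[ti]), int(dwells[ti + 1]),
            )
        )
    order = np.argsort([m[0] for m in matched]) if matched else []
    matched = [matched[i] for i in order]
    devs = [devs[i] for i in order]
    fp = tuple(int(d) for i, d in enumerate(d_idx) if i not in used_d)
    missed = tuple(int(t) for i, t in enumerate(t_idx) if i not in used_t)
    return MatchReport(
        matched_pairs=tuple(matched),
        false_positives=fp,
        missed_steps=missed,
        deviations_pct=tuple(devs),
    )


def aggregate_efficiency(reports, truth: StepModel) -> pd.Series:
    """Per-step detection fraction: for each true step, the fraction of
    replicates in which it was matched.  Indexed by true step index."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    counts = {int(t): 0 for t in truth.step_indices}
    for rep in reports:
        for t, _ in rep.matched_pairs:
            counts[int(t)] += 1
    frac = {t: c / len(reports) for t, c in counts.items()}
    return pd.Series(frac, name="detection_fraction")


def summarize_counts(values) -> pd.Series:
    """Min / 1st Qu. / Median / Mean / 3rd Qu. / Max summary row, in the
    format of the reference summary tables."""
    v = np.asarray(list(values), dtype=float)
    return pd.Series(
        {
            "Min.": float(np.min(v)),
            "1st Qu.": float(np.quantile(v, 0.25)),
            "Median": float(np.median(v)),
            "Mean": float(np.mean(v)),
            "3rd Qu.": float(np.quantile(v, 0.75)),
            "Max.": float(np.max(v)),
        }
    )
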