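"""Candidate step locations via a multi-window quantile-contrast statistic.

Backward model selection needs a superset of plausible step locations to
start from.  For a window of half-width ``w`` centred at sample ``i``, the
statistic

    eta_{i,w} = (1/3) * sum_q (q_left - q_right)^2 / R^2

compares the 0.25/0.5/0.75 quantiles of the left half {y_{i-w}..y_i} and the
right half {y_i..y_{i+w}}, normalized by the squared range R of the full
window, so 0 <= eta <= 1.  Quartiles (rather than a single mean, as in a
sliding t-test) make the contrast sensitive to changes in the whole shape of
the local distribution.  eta peaks at abrupt mean shifts; scanning a family
of window sizes makes the procedure insensitive to data bandwidth, and the
union of above-threshold local maxima over all windows is the candidate
superset C_L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from ._rolling import trailing_quartiles

__all__ = [
    "EtaProfile",
    "CandidateSet",
    "default_windows",
    "eta_at",
    "eta_profile",
    "build_superset",
]

_QUARTILES = (0.25, 0.5, 0.75)


def default_windows(n: int | None = None) -> tuple[int, ...]:
    """The default window half-width family: 10..100 in steps of 10 and
    100..1000 in steps of 25, truncated to w < n/2 when ``n`` is given."""
    ws = sorted(set(range(10, 101, 10)) | set(range(100, 1001, 25)))
    if n is not None:
        ws = [w for w in ws if w < n / 2]
    return tuple(ws)


@dataclass(frozen=True)
class EtaProfile:
    """eta_{i,w} for one window half-width at every index of a trace."""

    window_halfwidth: int
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(self.values.size),
                "window": self.window_halfwidth,
                "eta": self.values,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CandidateSet:
    """The superset C_L of plausible step indices.

    ``provenance`` maps each retained index to the list of
    ``(window_halfwidth, eta)`` nominations that survived merging into it.
    """

    indices: np.ndarray
    threshold_quantile: float
    provenance: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.indices.size)

    def best_eta(self) -> np.ndarray:
        return np.array(
            [max(e for _, e in self.provenance[int(i)]) for i in self.indices]
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for i in self.indices:
            for w, e in self.provenance.get(int(i), []):
                rows.append((int(i), w, e))
        return pd.DataFrame(rows, columns=["index", "window", "eta"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def eta_at(trace, i: int, w: int) -> float:
    """eta at a single index, shrinking the window at the series ends.

    Near the ends the half-width is reduced to ``min(w, i, n-1-i)`` so the
    full window stays inside the trace; by convention eta is 0 where the
    shrunken half-width is < 1 (indices 0 and n-1) or where the window range
    is 0.
    """
    x = np.asarray(trace, dtype=float).ravel()
    n = x.size
    if not 0 <= i < n:
        raise IndexError(f"index {i} outside series of length {n}")
    w_eff = min(w, i, n - 1 - i)
    if w_eff < 1:
        return 0.0
    window = x[i - w_eff : i + w_eff + 1]
    r = np.ptp(window)
    if r == 0.0:
        return 0.0
    ql = np.quantile(x[i - w_eff : i + 1], _QUARTILES)
    qr = np.quantile(x[i : i + w_eff + 1], _QUARTILES)
    return float(np.mean((ql - qr) ** 2) / r**2)


def eta_profile(trace, w: int) -> EtaProfile:
    """eta at every index of the trace for one window half-width.

    The interior (where the full window fits) is computed with an O(n*w)
    rolling sorted-buffer kernel; the right half of the window at index i is
    the trailing window ending at i+w, so a single pass serves both halves.
    Ends fall back to direct evaluation with shrunken windows.
    """
    x = np.ascontiguousarray(trace, dtype=float).ravel()
    n = x.size
    if w < 2:
        raise ValueError("window half-width must be >= 2")
    vals = np.zeros(n)
    lo, hi = w, n - 1 - w  # inclusive range where the full window fits
    if hi >= lo:
        tq = trailing_quartiles(x, w)
        ql = tq[lo : hi + 1]  # quartiles of x[i-w .. i]
        qr = tq[lo + w : hi + w + 1]  # quartiles of x[i .. i+w]
        msd = np.mean((ql - qr) ** 2, axis=1)
        size = 2 * w + 1
        rng_full = maximum_filter1d(x, size) - minimum_filter1d(x, size)
        r = rng_full[lo : hi + 1]
        core = np.where(r > 0.0, msd / np.where(r > 0.0, r, 1.0) ** 2, 0.0)
        vals[lo : hi + 1] = core
    for i in range(0, min(lo, n)):
        vals[i] = eta_at(x, i, w)
    for i in range(max(hi + 1, 0), n):
        if i >= lo:
            vals[i] = eta_at(x, i, w)
    return EtaProfile(window_halfwidth=w, values=vals)


def _local_maxima(vals: np.ndarray, horizon: int, threshold: float) -> np.ndarray:
    """Local peaks: indices whose value exceeds every other value within
    +/-horizon samples and exceeds the threshold.

    A plateau (a run of consecutive indices sharing the maximal value, as
    happens on noiseless steps) counts as one peak, represented by its
    central index; ties with non-contiguous equal values are rejected.
    """
    n = vals.size
    size = 2 * horizon + 1
    mf = maximum_filter1d(vals, size)
    cand = np.flatnonzero((vals >= mf) & (vals > threshold))
    keep = []
    start = 0
    while start < cand.size:
        stop = start
        while (
            stop + 1 < cand.size
            and cand[stop + 1] == cand[stop] + 1
            and vals[cand[stop + 1]] == vals[cand[start]]
        ):
            stop += 1
        run = cand[start : stop + 1]
        # plateaus on clean steps are symmetric about the half-sample
        # boundary t-0.5; rounding the centre up lands on the step index t
        rep = int(run[run.size // 2])
        lo = max(0, rep - horizon)
        hi = min(n, rep + horizon + 1)
        eq = np.flatnonzero(vals[lo:hi] == vals[rep]) + lo
        if np.all(np.diff(eq) == 1):  # all ties contiguous -> one plateau
            keep.append(rep)
        start = stop + 1
    return np.asarray(keep, dtype=int)


def build_superset(
    trace,
    windows=None,
    threshold_quantile: float = 0.90,
    merge_tol: int = 5,
    cap: int | None = None,
) -> CandidateSet:
    """Build the candidate superset C_L.

    For each window half-width, local maxima of the eta profile above that
    window's ``threshold_quantile`` of eta values are nominated (peak horizon
    ``max(2, w // 10)`` samples).  Nominations are pooled over windows and
    near-duplicates closer than ``merge_tol`` samples are collapsed onto the
    nomination with the largest eta.  Indices 0 and n-1 are never candidates.
    ``cap`` keeps only the strongest ``cap`` candidates (by best eta) as a
    computational guard.
    """
    x = np.asarray(trace, dtype=float).ravel()
    n = x.size
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    if windows is None:
        windows = default_windows(n)
    windows = sorted({int(w) for w in windows})
    if not windows:
        raise ValueError("windows must be non-empty")
    if np.ptp(x) == 0.0:
        return CandidateSet(
            indices=np.empty(0, dtype=int),
            threshold_quantile=threshold_quantile,
        )

    nominations: list[tuple[float, int, int]] = []  # (eta, index, window)
    for w in windows:
        prof = eta_profile(x, w).values
        thresh = float(np.quantile(prof, threshold_quantile))
        horizon = max(2, w // 10)
        for i in _local_maxima(prof, horizon, thresh):
            if 0 < i < n - 1:
                nominations.append((float(prof[i]), int(i), w))

    # Collapse near-duplicates onto the largest-eta nomination: nominations
    # are visited in descending eta order and attach to an already-accepted
    # index within merge_tol samples (the nearest one) if there is one.
    # Eta ties (exact on noiseless steps) go to the smallest window, which
    # localizes the change point most sharply.
    import bisect

    nominations.sort(key=lambda t: (-t[0], t[2], t[1]))
    accepted: list[int] = []  # kept sorted by index
    provenance: dict[int, list[tuple[int, float]]] = {}
    for eta_val, idx, w in nominations:
        pos = bisect.bisect_left(accepted, idx)
        home = None
        best_d = merge_tol
        for j in (pos - 1, pos):
            if 0 <= j < len(accepted) and abs(accepted[j] - idx) < best_d:
                best_d = abs(accepted[j] - idx)
                home = accepted[j]
        if home is None:
            bisect.insort(accepted, idx)
            home = idx
        provenance.setdefault(home, []).append((w, eta_val))

    if cap is not None and len(accepted) > cap:
        accepted.sort(key=lambda j: -max(e for _, e in provenance[j]))
        accepted = accepted[:cap]
        provenance = {j: provenance[j] for j in accepted}
    accepted.sort()
    return CandidateSet(
        indices=np.asarray(accepted, dtype=int),
        threshold_quantile=threshold_quantile,
        provenance=provenance,
    )
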