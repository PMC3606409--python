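"""Trace and result I/O.

Traces are plain delimited text: either two columns (time in seconds,
value) or one column of values plus an explicit sampling rate.  Step tables
are TSV, run reports JSON; identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "read_trace",
    "write_trace",
    "read_step_table",
    "write_results",
    "fit_to_step_frame",
]

_REL_TOL_UNIFORM = 1e-6


class TraceFormatError(ValueError):
    """Raised for malformed trace files."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled real-valued series."""

    values: np.ndarray
    dt: float
    units_label: str = "units"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if v.size < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        content = fh.read()
    body = [ln for ln in content.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise TraceFormatError(f"empty trace file: {path}")
    sep = "," if "," in body[0] else r"\s+"
    import io as _io

    try:
        df = pd.read_csv(_io.StringIO(content), sep=sep, header=None,
                         comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as err:
        raise TraceFormatError(f"malformed trace file {path}: {err}") from None
    # optional single header row: drop it if non-numeric
    first = df.iloc[0]
    try:
        first.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
        if df.empty:
            raise TraceFormatError(f"trace file has a header but no data: {path}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as err:
        raise TraceFormatError(f"non-numeric row in trace file {path}: {err}")
    if df.isna().any().any():
        raise TraceFormatError(f"missing values in trace file: {path}")
    return df.reset_index(drop=True)


def read_trace(path, sampling_rate: float | None = None,
               units_label: str = "units") -> Trace:
    """Read a trace from delimited text.

    Two columns are interpreted as (time_s, value) and must be uniformly
    sampled within relative tolerance 1e-6; one column requires
    ``sampling_rate`` (Hz).
    """
    df = _read_table(path)
    if df.shape[1] == 1:
        if sampling_rate is None:
            raise TraceFormatError(
                "one-column trace requires an explicit sampling rate"
            )
        return Trace(df.iloc[:, 0].to_numpy(), dt=1.0 / sampling_rate,
                     units_label=units_label)
    if df.shape[1] != 2:
        raise TraceFormatError(
            f"expected 1 or 2 columns, found {df.shape[1]} in {path}"
        )
    t = df.iloc[:, 0].to_numpy()
    v = df.iloc[:, 1].to_numpy()
    if t.size < 2:
        raise TraceFormatError("two-column trace needs at least two rows")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.any(np.abs(dts - dt) > _REL_TOL_UNIFORM * max(abs(dt), 1e-12)):
        raise TraceFormatError(
            f"non-uniform timestamps in {path} (median dt = {dt:g} s)"
        )
    return Trace(v, dt=dt, units_label=units_label)


def write_trace(trace: Trace, path) -> None:
    """Write a two-column (time_s, value) TSV; full-precision round trip."""
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def fit_to_step_frame(fit) -> pd.DataFrame:
    """Step table for a FitResult: step_index, time_s, size, se, t_p_value."""
    model = fit.model
    return pd.DataFrame(
        {
            "step_index": model.step_indices,
            "time_s": model.step_indices * model.dt,
            "size": model.step_sizes,
            "se": fit.standard_errors[1:],
            "t_p_value": fit.p_values,
        }
    )


def model_to_step_frame(model) -> pd.DataFrame:
    """Step table for a bare StepModel (no inference columns)."""
    return pd.DataFrame(
        {
            "step_index": model.step_indices,
            "time_s": model.step_indices * model.dt,
            "size": model.step_sizes,
            "se": np.nan,
            "t_p_value": np.nan,
        }
    )


def read_step_table(path, n: int, dt: float = 1.0):
    """Read a step table TSV back into a StepModel (baseline 0 unless a
    '# baseline:' comment is present)."""
    from .stepfit import StepModel

    baseline = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# baseline:"):
                baseline = float(line.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    return StepModel(
        baseline=baseline,
        step_indices=df["step_index"].to_numpy(dtype=int),
        step_sizes=df["size"].to_numpy(dtype=float),
        n=n,
        dt=dt,
    )


def write_step_table(frame: pd.DataFrame, path, baseline: float | None = None) -> None:
    with open(path, "w") as fh:
        if baseline is not None:
            fh.write(f"# baseline: {baseline!r}\n")
        frame.to_csv(fh, sep="\t", index=False,
                     float_format=lambda x: repr(float(x)))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(fit, tsv_path, json_path, config=None) -> None:
    """Write the step table (TSV) and the run report (JSON) for a fit.

    The JSON report carries the selected model, the elimination path with
    its information criteria, the AR noise model used for whitening, and an
    echo of the configuration.
    """
    from . import __version__

    write_step_table(fit_to_step_frame(fit), tsv_path,
                     baseline=fit.model.baseline)
    report = {
        "tool": "stepgls",
        "version": __version__,
        "n_samples": fit.model.n,
        "dt_s": fit.model.dt,
        "n_steps": fit.model.k,
        "baseline": fit.model.baseline,
        "step_indices": fit.model.step_indices,
        "step_sizes": fit.model.step_sizes,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "sigma2": fit.sigma2,
        "n_eff": fit.n_eff,
        "noise": {
            "order": fit.noise.order,
            "coefficients": list(fit.noise.coefficients),
            "innovation_sd": fit.noise.innovation_sd,
        },
        "bic_path": list(fit.path) if fit.path is not None else None,
        "config": config.to_dict() if config is not None else None,
    }
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
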