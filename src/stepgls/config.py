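"""Run configuration for the detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Settings for the full detection pipeline.

    Defaults reproduce the reference analysis: window half-widths 10..100
    step 10 plus 100..1000 step 25 (truncated to w < n/2 at run time), eta
    threshold at the 0.90 quantile, BIC model selection, AR order bounded by
    20.  ``assume_iid`` skips noise estimation and whitening, i.e. fits as if
    the noise were Gaussian white noise even when it is not.
    """

    windows: tuple[int, ...] | None = None
    threshold_quantile: float = 0.90
    assume_iid: bool = False
    max_ar_order: int = 20
    criterion: str = "BIC"
    seed: int = 0
    candidate_cap: int = 500
    merge_tol: int = 5
    reestimate_ar: bool = False

    def __post_init__(self) -> None:
        crit = self.criterion.upper()
        if crit not in ("AIC", "BIC"):
            raise ValueError("criterion must be 'AIC' or 'BIC'")
        self.criterion = crit
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["windows"] is not None:
            d["windows"] = list(d["windows"])
        return d
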