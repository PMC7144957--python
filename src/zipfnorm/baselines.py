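"""Simplified pairwise baseline normalizers: TC, MED, UQ, TMM, RLE.

Each method yields a single linear factor sigma (gamma = 1) aligning a
target profile to a reference profile:

* TC  -- ratio of total counts,
* MED -- ratio of medians,
* UQ  -- ratio of upper quartiles,
* TMM -- exp of the mean per-gene log ratio after trimming a fraction of
  the M-values from both ends,
* RLE -- exp of the median per-gene log ratio.

These are deliberately the plain pairwise formulations — a 30% symmetric
M-trim and an unweighted mean/median — NOT the canonical edgeR
``calcNormFactors`` (no A-trimming, no precision weights) or the DESeq
geometric-mean size factors; do not expect numerical parity with those
tools.

Zero handling follows a cascade: genes zero in BOTH profiles are dropped
first; if the resulting statistic is invalid (zero median/quartile,
non-finite trimmed mean or median of M), genes zero in EITHER profile are
dropped and the statistic recomputed.  The path taken is recorded in the
parameter diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizationParams
from .zipf_core import ExpressionProfile

__all__ = ["BaselineOptions", "baseline_factor", "summarize_factors", "BASELINE_METHODS"]

BASELINE_METHODS = ("TC", "MED", "UQ", "TMM", "RLE")


@dataclass(frozen=True)
class BaselineOptions:
    trim_fraction: float = 0.30  # trimmed from EACH end of the sorted M-values
    quartile_level: float = 0.75
    zero_policy: str = "auto_cascade"  # auto_cascade | both_zero_only | either_zero

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if not (0.0 < self.quartile_level < 1.0):
            raise ValueError("quartile_level must lie in (0, 1)")
        if self.zero_policy not in ("auto_cascade", "both_zero_only", "either_zero"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")


def _filtered(t: np.ndarray, r: np.ndarray, policy: str) -> tuple[np.ndarray, np.ndarray]:
    if policy == "both_zero_only":
        keep = ~((t == 0) & (r == 0))
    else:  # either_zero
        keep = (t > 0) & (r > 0)
    return t[keep], r[keep]


def _statistic(method: str, t: np.ndarray, r: np.ndarray, opts: BaselineOptions) -> float:
    """sigma for one zero-policy stage; NaN signals an invalid statistic."""
    if t.size == 0 or r.size == 0:
        return np.nan
    if method == "MED":
        mt, mr = np.median(t), np.median(r)
        return mt / mr if mt > 0 and mr > 0 else np.nan
    if method == "UQ":
        qt = np.quantile(t, opts.quartile_level)
        qr = np.quantile(r, opts.quartile_level)
        return qt / qr if qt > 0 and qr > 0 else np.nan
    # TMM / RLE work on M-values; zero in one profile gives an infinite M
    with np.errstate(divide="ignore"):
        m = np.log(t) - np.log(r)
    if method == "TMM":
        m = np.sort(m)
        k = int(np.floor(opts.trim_fraction * m.size))
        kept = m[k : m.size - k]
        if kept.size == 0:
            return np.nan
        mean = kept.mean()
        return float(np.exp(mean)) if np.isfinite(mean) else np.nan
    if method == "RLE":
        med = np.median(m)
        return float(np.exp(med)) if np.isfinite(med) else np.nan
    raise ValueError(f"unknown baseline method {method!r}")


def baseline_factor(
    method: str,
    target: ExpressionProfile,
    reference: ExpressionProfile,
    opts: BaselineOptions | None = None,
) -> NormalizationParams:
    """Linear factor sigma for ``method`` (target aligned to reference).

    sigma is oriented target/reference, so dividing the target by sigma
    brings it to the reference level.
    """
    opts = opts or BaselineOptions()
    method = method.upper()
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}; expected {BASELINE_METHODS}")
    t, r = target.counts, reference.counts
    if t.size != r.size:
        raise ValueError("target and reference must share the gene index")

    diagnostics: dict[str, object] = {}
    if method == "TC":
        total_r = r.sum()
        if total_r == 0:
            raise ValueError(f"TC: reference {reference.sample_id!r} has zero total count")
        sigma = float(t.sum() / total_r)
        diagnostics["zero_policy_path"] = "none"
    else:
        if opts.zero_policy == "auto_cascade":
            stages = ("both_zero_only", "either_zero")
        else:
            stages = (opts.zero_policy,)
        sigma = np.nan
        for stage in stages:
            sigma = _statistic(method, *_filtered(t, r, stage), opts)
            if np.isfinite(sigma):
                diagnostics["zero_policy_path"] = stage
                break
        if not np.isfinite(sigma):
            raise ValueError(
                f"{method}: no valid factor for sample {target.sample_id!r} "
                f"after zero-handling cascade (excessive zeros or tied zeros)"
            )
    return NormalizationParams(
        sigma=sigma,
        gamma=1.0,
        method=method,
        reference_id=reference.sample_id,
        estimator="ols",
        diagnostics=diagnostics,
    )


def summarize_factors(params_list: list[NormalizationParams]) -> pd.DataFrame:
    """Summary table of sigma estimates, one row per method.

    Columns: Min., 1st Qu., Median, Mean, 3rd Qu., Max., SD, Scal Up
    (fraction of factors below 1 — dividing by sigma < 1 scales a profile
    up) and No Chng (fraction exactly 1).
    """
    if not params_list:
        raise ValueError("empty parameter list")
    frame = pd.DataFrame(
        {"method": [p.method for p in params_list], "sigma": [p.sigma for p in params_list]}
    )
    rows = {}
    for method, grp in frame.groupby("method", sort=False):
        s = grp["sigma"].to_numpy()
        rows[method] = {
            "Min.": s.min(),
            "1st Qu.": np.quantile(s, 0.25),
            "Median": np.median(s),
            "Mean": s.mean(),
            "3rd Qu.": np.quantile(s, 0.75),
            "Max.": s.max(),
            "SD": s.std(ddof=1) if s.size > 1 else 0.0,
            "Scal Up": float(np.mean(s < 1.0)),
            "No Chng": float(np.mean(s == 1.0)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "Method"
    return out
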