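"""Zipf-plot based normalization (ZN): estimate (sigma, gamma) and apply them.

A target profile ``Y`` is normalized against a reference ``X`` as

    Y' = (Y / sigma) ** gamma

where ``sigma > 0`` is a linear rescaling factor (a horizontal shift of the
Zipf plot by ``log sigma``) and ``gamma > 0`` a power-transform exponent that
rotates the tail so the two fitted tail slopes agree.  The linear scheme
(``gamma = 1``) estimates ``log sigma`` as the group coefficient in a pooled
OLS of log value on log rank and a 0/1 group indicator over the upper-tail
points of both profiles; the full scheme first estimates ``gamma`` as the
ratio of the two tail slopes, then estimates ``sigma`` on the
power-transformed target tail so the pair is jointly consistent with the
transform above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .zipf_core import (
    DEFAULT_MIN_TAIL_POINTS,
    DEFAULT_RANK_CUTOFF_LOG,
    ExpressionProfile,
    TailFit,
    ZipfCurve,
    compute_zipf,
    fit_tail,
    tail_mask,
)

__all__ = [
    "NormalizationParams",
    "PooledTailPoints",
    "estimate_gamma",
    "estimate_log_sigma",
    "normalize_profile",
    "normalize_pair",
    "select_reference",
    "normalize_matrix",
    "METHODS",
]

METHODS = ("ZN-linear", "ZN-full", "TC", "MED", "UQ", "TMM", "RLE")
_LINEAR_ONLY = frozenset(m for m in METHODS if m != "ZN-full")


@dataclass(frozen=True)
class NormalizationParams:
    """A (sigma, gamma) pair with provenance.

    ``sigma`` divides the target profile; ``gamma`` is the exponent applied
    afterwards.  Every method except ``ZN-full`` is purely linear and must
    carry ``gamma = 1``.
    """

    sigma: float
    gamma: float
    method: str
    reference_id: str
    estimator: str = "ols"
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.method in _LINEAR_ONLY and self.gamma != 1.0:
            raise ValueError(f"method {self.method!r} is linear; gamma must be 1")


@dataclass(frozen=True)
class PooledTailPoints:
    """Upper-tail points of two profiles stacked for the pooled regression.

    ``group`` is 0 for reference points and 1 for target points.
    """

    log_value: np.ndarray
    log_rank: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.log_value) == len(self.log_rank) == len(self.group)):
            raise ValueError("log_value, log_rank and group must have equal length")
        if not (np.any(self.group == 0) and np.any(self.group == 1)):
            raise ValueError("pooled points must contain both groups")


def estimate_gamma(fit_x: TailFit, fit_y: TailFit) -> float:
    """Power-transform exponent from two tail fits: slope_y / slope_x.

    The Zipf slope of ``Y**gamma`` is ``slope_y / gamma``; matching it to the
    reference slope gives ``gamma = slope_y / slope_x``.  Both slopes must be
    strictly negative (decreasing heavy tails).
    """
    if fit_x.slope >= 0 or fit_y.slope >= 0:
        raise ValueError(
            "tail slopes must be strictly negative for a power-law tail; "
            f"got reference {fit_x.slope:.4g}, target {fit_y.slope:.4g}"
        )
    return fit_y.slope / fit_x.slope


def pool_tail_points(
    curve_x: ZipfCurve,
    curve_y: ZipfCurve,
    rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
    gamma_y: float = 1.0,
) -> PooledTailPoints:
    """Stack the two upper tails; target log values are scaled by ``gamma_y``."""
    parts = []
    for label, curve, grp in (("reference", curve_x, 0), ("target", curve_y, 1)):
        mask = tail_mask(curve, rank_cutoff_log)
        if int(mask.sum()) < min_tail_points:
            raise ValueError(
                f"{label} profile has {int(mask.sum())} tail points with "
                f"log(rank) < {rank_cutoff_log}; need {min_tail_points}"
            )
        log_z = np.log(curve.values[mask])
        if grp == 1 and gamma_y != 1.0:
            log_z = gamma_y * log_z
        parts.append((log_z, np.log(curve.ranks[mask]), np.full(mask.sum(), grp)))
    return PooledTailPoints(
        log_value=np.concatenate([p[0] for p in parts]),
        log_rank=np.concatenate([p[1] for p in parts]),
        group=np.concatenate([p[2] for p in parts]).astype(float),
    )


def estimate_log_sigma(
    curve_x: ZipfCurve,
    curve_y: ZipfCurve,
    rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
    gamma_y: float = 1.0,
) -> float:
    """Pooled-OLS estimate of log(sigma).

    Fits ``Z = a + b*R + c*G`` over the stacked tail points, where Z is the
    log value (the target's scaled by ``gamma_y`` when the full scheme has
    already fixed the exponent), R the log rank and G the group indicator.
    The group coefficient ``c`` is the horizontal tail shift, i.e.
    ``gamma_y * log(sigma)``; the returned value is ``c / gamma_y`` so that
    ``(Y / sigma) ** gamma_y`` aligns the tails.  The coefficient is read as
    a shift in log space: a target tail to the right of the reference yields
    ``sigma > 1`` and division moves it back down.
    """
    pooled = pool_tail_points(curve_x, curve_y, rank_cutoff_log, min_tail_points, gamma_y)
    design = np.column_stack(
        [np.ones(len(pooled.group)), pooled.log_rank, pooled.group]
    )
    coef, _, rank, _ = np.linalg.lstsq(design, pooled.log_value, rcond=None)
    if rank < 3:
        raise ValueError("singular pooled design; tails carry no group contrast")
    return float(coef[2]) / gamma_y


def normalize_profile(
    profile: ExpressionProfile, params: NormalizationParams
) -> ExpressionProfile:
    """Apply ``y -> (y / sigma) ** gamma`` entrywise; zeros stay exactly zero."""
    y = profile.counts
    out = np.zeros_like(y)
    pos = y > 0
    out[pos] = (y[pos] / params.sigma) ** params.gamma
    return ExpressionProfile(sample_id=profile.sample_id, counts=out)


def normalize_pair(
    reference: ExpressionProfile,
    target: ExpressionProfile,
    scheme: str = "linear",
    rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
    sigma_on_transformed: bool = True,
) -> NormalizationParams:
    """Estimate ZN parameters for one target against one reference.

    scheme "linear" fixes gamma = 1; scheme "full" first sets gamma from the
    two tail slopes, then (by default) estimates sigma on the
    gamma-transformed target tail so (sigma, gamma) are jointly consistent.
    ``sigma_on_transformed=False`` estimates sigma from the raw tails
    instead.
    """
    if scheme not in ("linear", "full"):
        raise ValueError(f"scheme must be 'linear' or 'full', got {scheme!r}")
    curve_x = compute_zipf(reference)
    curve_y = compute_zipf(target)
    fit_x = fit_tail(curve_x, rank_cutoff_log, min_tail_points)
    fit_y = fit_tail(curve_y, rank_cutoff_log, min_tail_points)
    diagnostics: dict[str, Any] = {
        "slope_reference": fit_x.slope,
        "slope_target": fit_y.slope,
        "r2_reference": fit_x.r_squared,
        "r2_target": fit_y.r_squared,
    }
    if scheme == "linear":
        gamma = 1.0
        log_sigma = estimate_log_sigma(
            curve_x, curve_y, rank_cutoff_log, min_tail_points
        )
        method = "ZN-linear"
    else:
        gamma = estimate_gamma(fit_x, fit_y)
        gamma_for_sigma = gamma if sigma_on_transformed else 1.0
        log_sigma = estimate_log_sigma(
            curve_x, curve_y, rank_cutoff_log, min_tail_points, gamma_y=gamma_for_sigma
        )
        method = "ZN-full"
        diagnostics["sigma_on_transformed"] = sigma_on_transformed
    return NormalizationParams(
        sigma=float(np.exp(log_sigma)),
        gamma=float(gamma),
        method=method,
        reference_id=reference.sample_id,
        estimator="ols",
        diagnostics=diagnostics,
    )


def select_reference(matrix: pd.DataFrame, strategy: str = "fewest_zeros") -> str:
    """Pick the reference sample.

    ``"fewest_zeros"`` returns the column with the fewest zero entries (ties
    broken by column order); any other string is treated as a user-supplied
    sample id and must be a column of the matrix.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty matrix; no reference can be selected")
    if strategy == "fewest_zeros":
        zeros = (matrix.to_numpy() == 0).sum(axis=0)
        return str(matrix.columns[int(np.argmin(zeros))])
    if strategy in matrix.columns.astype(str).tolist():
        return strategy
    raise ValueError(f"unknown reference sample id {strategy!r}")


def normalize_matrix(
    matrix: pd.DataFrame,
    reference: str,
    scheme: str = "linear",
    rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
    refine: bool = False,
    sigma_on_transformed: bool = True,
) -> tuple[pd.DataFrame, list[NormalizationParams]]:
    """Normalize every column pairwise against the reference column.

    The reference column is returned unchanged with (sigma, gamma) = (1, 1)
    recorded.  With ``refine=True`` each OLS estimate is polished by the
    grid search minimizing the two-sample KS distance (see
    :mod:`zipfnorm.refine`).  A column whose tail cannot be fitted aborts
    the run with the column named.
    """
    if reference not in matrix.columns:
        raise ValueError(f"reference column {reference!r} not in matrix")
    ref_profile = ExpressionProfile(str(reference), matrix[reference].to_numpy())
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    params_list: list[NormalizationParams] = []
    for col in matrix.columns:
        profile = ExpressionProfile(str(col), matrix[col].to_numpy())
        if col == reference:
            params = NormalizationParams(
                sigma=1.0,
                gamma=1.0,
                method="ZN-full" if scheme == "full" else "ZN-linear",
                reference_id=str(reference),
                estimator="ols",
                diagnostics={"is_reference": True},
            )
            out[col] = profile.counts
        else:
            try:
                params = normalize_pair(
                    ref_profile,
                    profile,
                    scheme=scheme,
                    rank_cutoff_log=rank_cutoff_log,
                    min_tail_points=min_tail_points,
                    sigma_on_transformed=sigma_on_transformed,
                )
            except ValueError as exc:
                raise ValueError(f"column {col!r}: {exc}") from exc
            if refine:
                from .refine import GridSpec, refine_params

                params, _, _ = refine_params(
                    ref_profile, profile, GridSpec(center=(params.sigma, params.gamma))
                )
            out[col] = normalize_profile(profile, params).counts
        params_list.append(params)
    return out, params_list


def params_table(
    sample_ids: list[str], params_list: list[NormalizationParams]
) -> pd.DataFrame:
    """Tidy per-sample parameter table (sample order preserved)."""
    if len(sample_ids) != len(params_list):
        raise ValueError("sample_ids and params_list must have equal length")
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sigma": [p.sigma for p in params_list],
            "gamma": [p.gamma for p in params_list],
            "method": [p.method for p in params_list],
            "reference_id": [p.reference_id for p in params_list],
            "estimator": [p.estimator for p in params_list],
        }
    )
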