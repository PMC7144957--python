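"""Zipf curves of count profiles and least-squares fits to their upper tails.

A Zipf plot displays log rank against log value for the distinct positive
measures of a right-skewed sample.  For a value ``z_i`` the rank is the
number of observations greater than or equal to ``z_i``; when the upper tail
follows a power law with index ``kappa`` (density proportional to
``x**-kappa`` above some threshold) the plot is linear in the tail with
slope ``1 - kappa < 0``.  Everything here uses the natural logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionProfile",
    "ZipfCurve",
    "TailFit",
    "compute_zipf",
    "log_survival",
    "fit_tail",
    "DEFAULT_RANK_CUTOFF_LOG",
    "DEFAULT_MIN_TAIL_POINTS",
]

#: log-rank threshold defining the fitted upper tail: points with
#: log(rank) < 6, i.e. ranks up to floor(e**6) = 403.
DEFAULT_RANK_CUTOFF_LOG: float = 6.0

#: minimum number of distinct-value points required for a tail fit.
DEFAULT_MIN_TAIL_POINTS: int = 10


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's non-negative expression measures over a fixed gene index.

    Raw read counts are integers; normalized values may be fractional.
    """

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if counts.size == 0:
            raise ValueError("counts must be non-empty")
        if not np.all(np.isfinite(counts)):
            raise ValueError(f"profile {self.sample_id!r} has non-finite entries")
        if np.any(counts < 0):
            raise ValueError(f"profile {self.sample_id!r} has negative entries")
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return int(self.counts.size)

    @property
    def n_zero(self) -> int:
        return int(np.count_nonzero(self.counts == 0))


@dataclass(frozen=True)
class ZipfCurve:
    """Distinct positive values of a profile with frequencies and ranks.

    ``values`` is strictly decreasing (z_1 > ... > z_m, all positive),
    ``freqs`` the positive multiplicities, and ``ranks`` the cumulative sums
    ``r_i = f_1 + ... + f_i``, i.e. the number of measures >= z_i.  Zeros
    never appear among the values; they are accounted for only through
    ``n_total`` and ``n_zero``.
    """

    values: np.ndarray
    freqs: np.ndarray
    ranks: np.ndarray
    n_total: int
    n_zero: int

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.freqs) == len(self.ranks)):
            raise ValueError("values, freqs and ranks must have equal length")
        if np.any(np.diff(self.values) >= 0):
            raise ValueError("values must be strictly decreasing")
        if np.any(self.freqs < 1):
            raise ValueError("freqs must be >= 1")
        if int(self.ranks[-1]) != self.n_total - self.n_zero:
            raise ValueError("last rank must equal the number of positive measures")

    @property
    def n_distinct(self) -> int:
        return int(len(self.values))


@dataclass(frozen=True)
class TailFit:
    """OLS line fitted to the upper-tail points of a Zipf curve.

    The regression is log(rank) on log(value) over the distinct-value points
    with log(rank) below ``rank_cutoff_log``; under a power-law tail the
    slope estimates ``1 - kappa``, hence ``kappa = 1 - slope``.
    """

    slope: float
    intercept: float
    rank_cutoff_log: float
    n_points: int
    r_squared: float
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", 1.0 - self.slope)


def compute_zipf(profile: ExpressionProfile) -> ZipfCurve:
    """Build the Zipf curve (distinct positive values, frequencies, ranks).

    Raises
    ------
    ValueError
        If the profile has no positive measures.
    """
    x = profile.counts
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError(
            f"profile {profile.sample_id!r} has no positive measures; "
            "a Zipf curve is undefined"
        )
    values, freqs = np.unique(positive, return_counts=True)
    values = values[::-1]  # decreasing
    freqs = freqs[::-1]
    ranks = np.cumsum(freqs)
    return ZipfCurve(
        values=values,
        freqs=freqs,
        ranks=ranks,
        n_total=x.size,
        n_zero=int(np.count_nonzero(x == 0)),
    )


def log_survival(curve: ZipfCurve) -> np.ndarray:
    """Return (log z_i, log S(z_i)) pairs, S(z) = rank(z) / n_total.

    This is the Zipf plot shifted down by log(n_total) on the y-axis; the
    output is an (m, 2) array.
    """
    return np.column_stack(
        [np.log(curve.values), np.log(curve.ranks) - np.log(curve.n_total)]
    )


def tail_mask(curve: ZipfCurve, rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG) -> np.ndarray:
    """Boolean mask of the distinct-value points with log(rank) < cutoff."""
    return np.log(curve.ranks) < rank_cutoff_log


def fit_tail(
    curve: ZipfCurve,
    rank_cutoff_log: float = DEFAULT_RANK_CUTOFF_LOG,
    min_tail_points: int = DEFAULT_MIN_TAIL_POINTS,
) -> TailFit:
    """OLS of log(rank) on log(value) over the upper-tail points.

    Tail membership is decided by the log-rank cutoff (``log r_i < 6`` by
    default, i.e. ranks up to 403); each distinct value contributes one
    unweighted point, matching the plotted object.

    Raises
    ------
    ValueError
        If fewer than ``min_tail_points`` distinct values qualify.
    """
    mask = tail_mask(curve, rank_cutoff_log)
    n_points = int(mask.sum())
    if n_points < min_tail_points:
        raise ValueError(
            f"tail fit needs at least {min_tail_points} points with "
            f"log(rank) < {rank_cutoff_log}, found {n_points}"
        )
    log_z = np.log(curve.values[mask])
    log_r = np.log(curve.ranks[mask])
    design = np.column_stack([np.ones(n_points), log_z])
    coef, _, _, _ = np.linalg.lstsq(design, log_r, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = log_r - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((log_r - log_r.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return TailFit(
        slope=slope,
        intercept=intercept,
        rank_cutoff_log=rank_cutoff_log,
        n_points=n_points,
        r_squared=r_squared,
    )


def export_zipf_coordinates(curve: ZipfCurve) -> np.ndarray:
    """(m, 2) array of (log value, log rank) pairs for external plotting."""
    return np.column_stack([np.log(curve.values), np.log(curve.ranks)])
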