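"""Benchmarking normalizations: per-gene CV, invariant sets, agreement, MA data.

If a normalization works and most genes are not differentially expressed,
a set of strongly and stably expressed genes — "invariants" — should show
small coefficients of variation (CV = sd / mean) across the normalized
samples.  Methods are compared by the overlap of their invariant sets and
by the Spearman correlation of their CV vectors; MA data (per-gene log
ratio M against average log expression A) diagnose a single pair of
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .zipf_core import ExpressionProfile

__all__ = [
    "InvariantReport",
    "MAData",
    "gene_cv",
    "select_invariants",
    "agreement",
    "ma_data",
    "ma_loess",
]


@dataclass(frozen=True)
class InvariantReport:
    """Per-gene CVs, eligibility and (once selected) the invariant set.

    ``gene_cv`` holds NaN for ineligible genes (those with at least the
    zero-exclusion fraction of zeros).  ``invariant_ids`` and ``cutoff_cv``
    are filled by :func:`select_invariants`.
    """

    gene_cv: pd.Series
    eligible_mask: pd.Series
    invariant_ids: pd.Index | None = None
    cutoff_cv: float | None = None

    @property
    def n_selected(self) -> int:
        return 0 if self.invariant_ids is None else len(self.invariant_ids)

    @property
    def n_eligible(self) -> int:
        return int(self.eligible_mask.sum())


@dataclass(frozen=True)
class MAData:
    """M = log(X) - log(Y) and A = (log(X) + log(Y)) / 2 per gene.

    Only genes positive in both profiles appear (log of zero is undefined).
    """

    m: np.ndarray
    a: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.m) == len(self.a) == len(self.gene_ids)):
            raise ValueError("m, a and gene_ids must have equal length")


def gene_cv(matrix: pd.DataFrame, zero_exclusion_fraction: float = 0.5) -> InvariantReport:
    """Per-gene CV over all samples, with an eligibility mask.

    CV uses the sample standard deviation (n-1 denominator) over ALL of a
    gene's normalized values, zeros included; the zero rule only gates
    eligibility: genes whose zero share reaches ``zero_exclusion_fraction``
    (default 50%) are excluded from invariant consideration.
    """
    if matrix.shape[1] < 2:
        raise ValueError("gene_cv needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    zero_frac = (values == 0).mean(axis=1)
    eligible = zero_frac < zero_exclusion_fraction
    mean = values.mean(axis=1)
    if np.any(eligible & (mean == 0)):
        raise ValueError("eligible gene with zero mean; inputs are inconsistent")
    sd = values.std(axis=1, ddof=1)
    cv = np.full(len(matrix), np.nan)
    cv[eligible] = sd[eligible] / mean[eligible]
    return InvariantReport(
        gene_cv=pd.Series(cv, index=matrix.index, name="cv"),
        eligible_mask=pd.Series(eligible, index=matrix.index, name="eligible"),
    )


def select_invariants(report: InvariantReport, n: int = 1000) -> InvariantReport:
    """Complete a report with the ``n`` eligible genes of smallest CV.

    Ties at the selection boundary are broken by gene-index order (stable
    sort); ``cutoff_cv`` is the largest selected CV.
    """
    eligible_cv = report.gene_cv[report.eligible_mask]
    if len(eligible_cv) < n:
        raise ValueError(f"only {len(eligible_cv)} eligible genes; cannot select {n}")
    order = np.argsort(eligible_cv.to_numpy(), kind="stable")
    selected = eligible_cv.index[order[:n]]
    cutoff = float(eligible_cv.loc[selected].max())
    return InvariantReport(
        gene_cv=report.gene_cv,
        eligible_mask=report.eligible_mask,
        invariant_ids=pd.Index(selected),
        cutoff_cv=cutoff,
    )


def agreement(reports: dict[str, InvariantReport]) -> pd.DataFrame:
    """Agreement matrix across methods.

    Lower triangle: number of common invariants between two methods.
    Diagonal: each method's cutoff CV.  Upper triangle: Spearman rank
    correlation (average ranks for ties) of the two CV vectors over genes
    eligible under both methods.
    """
    methods = list(reports)
    first = reports[methods[0]]
    for name, rep in reports.items():
        if rep.invariant_ids is None:
            raise ValueError(f"report {name!r} has no invariant selection")
        if not rep.gene_cv.index.equals(first.gene_cv.index):
            raise ValueError(f"report {name!r} has a mismatched gene index")
        if rep.n_selected != first.n_selected:
            raise ValueError("all reports must select the same number of invariants")
    out = pd.DataFrame(np.nan, index=methods, columns=methods, dtype=float)
    for i, mi in enumerate(methods):
        out.loc[mi, mi] = reports[mi].cutoff_cv
        for mj in methods[i + 1 :]:
            ri, rj = reports[mi], reports[mj]
            out.loc[mj, mi] = float(
                len(pd.Index(ri.invariant_ids).intersection(rj.invariant_ids))
            )
            both = ri.eligible_mask & rj.eligible_mask
            rho, _ = stats.spearmanr(ri.gene_cv[both], rj.gene_cv[both])
            out.loc[mi, mj] = float(rho)
    return out


def ma_data(profile_x: ExpressionProfile, profile_y: ExpressionProfile,
            gene_ids: np.ndarray | None = None) -> MAData:
    """MA coordinates for genes positive in both profiles (natural log)."""
    x, y = profile_x.counts, profile_y.counts
    if x.size != y.size:
        raise ValueError("profiles must share the gene index")
    if gene_ids is None:
        gene_ids = np.arange(x.size)
    pos = (x > 0) & (y > 0)
    if not np.any(pos):
        raise ValueError("no genes positive in both profiles")
    lx, ly = np.log(x[pos]), np.log(y[pos])
    return MAData(m=lx - ly, a=(lx + ly) / 2.0, gene_ids=np.asarray(gene_ids)[pos])


def ma_loess(data: MAData, span: float = 0.2) -> np.ndarray:
    """Loess-smoothed M against A (diagnostic only); returns (A, M̂) pairs.

    Delegates to statsmodels' lowess with ``frac=span``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    return lowess(data.m, data.a, frac=span, return_sorted=True)
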