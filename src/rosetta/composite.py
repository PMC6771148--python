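"""Composite pairwise-complete correlation matrix across a dataset pool.

The data-integration step of the pipeline: every Pearson correlation is
computed over the *pooled logical intersection* of subjects observing both
measures, across all constituent datasets. Pairs never co-observed inside a
single dataset can still be estimated if some dataset observes both. The
assembled matrix is in general indefinite and is smoothed to the nearest
correlation matrix before factoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .datapool import DataPool, MeasurementCatalog
from .errors import ConditioningError, ConvergenceError, CorrelationError

__all__ = [
    "CompositeCorrelation",
    "ConditioningReport",
    "pairwise_correlation",
    "nearest_psd",
    "conditioning_report",
]

#: measures with fewer joint observations than this cannot be correlated
MIN_JOINT_OBS = 3
#: eigenvalue tolerance for "positive semidefinite enough"
PSD_TOL = 1e-8
#: condition number above which the matrix is treated as numerically singular;
#: legitimate near-singular regimes (very high between-domain correlations)
#: reach ~1e9, so the gate sits well above that but far below float64 loss
COND_FAIL = 1e10
#: mean within-domain correlation below which factoring is refused
WITHIN_WARN = 0.2


@dataclass
class CompositeCorrelation:
    """Pairwise-complete composite correlation matrix with observation counts.

    Attributes
    ----------
    R : (p, p) correlations, catalog order, unit diagonal.
    N : (p, p) pairwise observation counts pooled over datasets.
    measure_ids : labels for rows/columns.
    psd_adjusted : True if a nearest-correlation projection was applied.
    min_eigenvalue_before : smallest eigenvalue before any smoothing.
    """

    R: np.ndarray
    N: np.ndarray
    measure_ids: tuple[str, ...]
    psd_adjusted: bool = False
    min_eigenvalue_before: float = float("nan")

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.R[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=list(self.measure_ids), columns=list(self.measure_ids))

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.N, index=list(self.measure_ids), columns=list(self.measure_ids))


def pairwise_correlation(pool: DataPool, min_obs: int = MIN_JOINT_OBS) -> CompositeCorrelation:
    """Assemble the composite correlation matrix from a pool.

    Each entry (i, j) is the Pearson correlation over all pooled subjects
    observing both i and j — the highest number of observations the pool can
    offer for that pair. Dataset-specific effects on correlations are
    deliberately ignored.

    Raises
    ------
    CorrelationError
        If some pair has fewer than ``min_obs`` joint observations, or a
        column has (pairwise) zero variance. Imputing such entries is out of
        scope; the input pool must cover every pair.
    """
    big = pool.concat()
    if big.empty:
        raise CorrelationError("empty pool: no subjects to correlate")
    measures = list(pool.catalog.measure_ids)
    big = big.reindex(columns=measures)

    mask = big.notna().to_numpy(dtype=np.int64)
    N = mask.T @ mask

    p = len(measures)
    thin = [
        (measures[i], measures[j], int(N[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if N[i, j] < min_obs
    ]
    if thin:
        desc = ", ".join(f"({a},{b}): {n} joint obs" for a, b, n in thin[:10])
        raise CorrelationError(
            f"pairwise correlation undefined for {len(thin)} measure pair(s) "
            f"with fewer than {min_obs} joint observations: {desc}"
        )

    flat = [m for m in measures if big[m].std(skipna=True) == 0 or big[m].count() < 2]
    if flat:
        raise CorrelationError(f"zero-variance column(s): {flat}")

    R = big.corr(method="pearson", min_periods=min_obs).to_numpy()
    bad = np.argwhere(~np.isfinite(R))
    if bad.size:
        i, j = bad[0]
        raise CorrelationError(
            f"correlation undefined for pair ({measures[i]}, {measures[j]}): "
            "zero variance on the joint subjects"
        )
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CompositeCorrelation(R=R, N=N, measure_ids=tuple(measures))


def nearest_psd(corr: CompositeCorrelation, tol: float = PSD_TOL) -> CompositeCorrelation:
    """Project the composite matrix onto the nearest correlation matrix.

    Pairwise-complete assembly does not guarantee positive semidefiniteness.
    If the smallest eigenvalue is already >= -tol the input is returned
    unchanged; otherwise an alternating-projections nearest-correlation
    smoothing (eigenvalue clipping at ``tol``, diagonal reset to one) is
    applied and flagged.
    """
    eigmin = float(np.linalg.eigvalsh(corr.R).min())
    if eigmin >= -tol:
        return replace(corr, psd_adjusted=False, min_eigenvalue_before=eigmin)
    with warnings.catch_warnings():
        # convergence is verified below by the eigenvalue check
        warnings.simplefilter("ignore", IterationLimitWarning)
        smoothed = corr_nearest(corr.R, threshold=max(tol, 1e-15), n_fact=200)
    smoothed = np.asarray(smoothed)
    eig_after = float(np.linalg.eigvalsh(smoothed).min())
    if eig_after < -tol:
        raise ConvergenceError(
            f"nearest-correlation projection did not converge: smallest "
            f"eigenvalue {eig_after:.3e} (gap {-eig_after - tol:.3e})"
        )
    np.fill_diagonal(smoothed, 1.0)
    return replace(
        corr, R=np.clip(smoothed, -1.0, 1.0), psd_adjusted=True, min_eigenvalue_before=eigmin
    )


@dataclass
class ConditioningReport:
    """Diagnostics deciding whether the composite matrix supports factoring.

    ``failed`` is True when the matrix is numerically singular or when the
    within-domain correlations are too weak to carry a factor structure —
    the regime in which pipeline output would be numerically meaningless,
    so downstream stages refuse to run.
    """

    condition_number: float
    mean_within_by_domain: dict[str, float] | None
    mean_abs_offdiag: float
    failed: bool
    messages: list[str]


def conditioning_report(
    corr: CompositeCorrelation,
    catalog: MeasurementCatalog | None = None,
    cond_threshold: float = COND_FAIL,
    within_warn: float = WITHIN_WARN,
) -> ConditioningReport:
    """Diagnose ill-conditioning / absent factor structure. Pure; never raises.

    When the catalog carries domain labels the check is the mean within-domain
    correlation per domain; without domains it falls back to the mean absolute
    off-diagonal correlation of the whole matrix.
    """
    R = corr.R
    p = R.shape[0]
    cond = float(np.linalg.cond(R))
    off = R[~np.eye(p, dtype=bool)]
    mean_abs = float(np.abs(off).mean()) if off.size else 0.0

    messages: list[str] = []
    failed = False
    if not np.isfinite(cond) or cond > cond_threshold:
        failed = True
        messages.append(
            f"correlation matrix numerically singular (condition number {cond:.3e} "
            f"> {cond_threshold:.0e})"
        )

    mean_within: dict[str, float] | None = None
    domains = catalog.domains if catalog is not None else None
    if domains:
        ids = list(corr.measure_ids)
        mean_within = {}
        for d in domains:
            idx = [ids.index(m) for m in catalog.measures_in_domain(d) if m in ids]
            if len(idx) < 2:
                continue
            block = R[np.ix_(idx, idx)]
            vals = block[~np.eye(len(idx), dtype=bool)]
            mean_within[d] = float(vals.mean())
        weak = {d: v for d, v in mean_within.items() if v < within_warn}
        if weak:
            failed = True
            messages.append(
                "within-domain correlations too weak for a factor structure: "
                + ", ".join(f"{d}: {v:.3f}" for d, v in sorted(weak.items()))
                + f" (threshold {within_warn})"
            )
    elif mean_abs < within_warn:
        failed = True
        messages.append(
            f"mean absolute off-diagonal correlation {mean_abs:.3f} < {within_warn}: "
            "no usable factor structure"
        )

    return ConditioningReport(
        condition_number=cond,
        mean_within_by_domain=mean_within,
        mean_abs_offdiag=mean_abs,
        failed=failed,
        messages=messages,
    )


def require_well_conditioned(report: ConditioningReport) -> None:
    """Raise ConditioningError if the report carries the failure flag."""
    if report.failed:
        raise ConditioningError("; ".join(report.messages) or "conditioning check failed")
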