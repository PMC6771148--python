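"""Common-factor extraction from a correlation matrix.

Principal-axis factoring with iterated communalities, an oblique rotation,
and Thurstone regression score weights. The factor correlation matrix Phi
produced here is the object the harmonizer later holds fixed across
datasets, so rotations must be oblique (an orthogonal rotation would pin
Phi to the identity and discard the between-trait information).

Rotation is solved by gradient-projection (statsmodels) restarted from
several random orthogonal starts; the best criterion value is kept. A
single GPA run from the identity is not reliable on matrices with strong
symmetric block structure — it can land in a degenerate local optimum in
which two factors collapse onto a shared direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import ortho_group
from statsmodels.multivariate.factor_rotation import rotate_factors

from .composite import CompositeCorrelation
from .errors import ConvergenceError, ExtractionError, SingularMatrixError

__all__ = ["FactorModel", "ExtractionConfig", "extract", "rotate", "score_weights"]

Rotation = Literal["oblimin", "promax", "none"]

#: fixed seed for the rotation restarts — rotation is deterministic given R
_ROTATION_SEED = 7451


@dataclass
class ExtractionConfig:
    """User-facing knobs of the factor step.

    k is always supplied by the user; the pipeline never infers the number
    of factors from the data.
    """

    k: int
    tol: float = 1e-6
    max_iter: int = 5000
    rotation: Rotation = "oblimin"
    n_rotation_starts: int = 10

    def __post_init__(self):
        if self.k < 1:
            raise ExtractionError(f"number of factors must be >= 1, got {self.k}")
        if self.rotation not in ("oblimin", "promax", "none"):
            raise ExtractionError(f"unknown rotation {self.rotation!r}")


@dataclass
class FactorModel:
    """Loadings, communalities, factor correlations and score weights.

    Lambda is on the standardized-variable (correlation) metric. Phi is the
    factor correlation matrix; W = R^-1 Lambda Phi are the regression score
    weights (None until :func:`score_weights` runs).
    """

    k: int
    Lambda: np.ndarray
    h2: np.ndarray
    Phi: np.ndarray
    measure_ids: tuple[str, ...]
    W: np.ndarray | None = None
    rotated: bool = False

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    def implied_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Phi Lambda' + diag(1 - h2)."""
        C = self.Lambda @ self.Phi @ self.Lambda.T
        C = C - np.diag(np.diag(C)) + np.eye(self.p)
        return C

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"F{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.Lambda, index=list(self.measure_ids), columns=cols)


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as initial communalities, with a
    max-|row correlation| fallback when R is near-singular."""
    p = R.shape[0]
    try:
        cond = np.linalg.cond(R)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        off = np.abs(R - np.eye(p))
        return off.max(axis=1)
    if np.any(smc < 0) or np.any(smc >= 1):
        off = np.abs(R - np.eye(p))
        return off.max(axis=1)
    return smc


def _canonicalize(Lambda: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve sign and order indeterminacy deterministically.

    Each factor's largest-magnitude loading is made positive; factors are
    then ordered by the row index of that loading so output labels are
    stable under refactoring of equivalent solutions.
    """
    L = Lambda.copy()
    P = Phi.copy()
    k = L.shape[1]
    anchors = np.empty(k, dtype=int)
    for j in range(k):
        i = int(np.argmax(np.abs(L[:, j])))
        anchors[j] = i
        if L[i, j] < 0:
            L[:, j] *= -1.0
            P[j, :] *= -1.0
            P[:, j] *= -1.0
    order = np.argsort(anchors, kind="stable")
    return L[:, order], P[np.ix_(order, order)]


def extract(corr: CompositeCorrelation, cfg: ExtractionConfig) -> FactorModel:
    """Principal-axis factoring with iterated communalities.

    The correlation matrix's diagonal is replaced by current communality
    estimates, the reduced matrix eigen-decomposed, loadings formed from the
    top-k eigenpairs, and communalities re-estimated from the loadings until
    the largest communality change falls below ``cfg.tol``.

    Raises
    ------
    ExtractionError
        If k >= p or a retained eigenvalue is non-positive (no common
        variance to support k factors).
    ConvergenceError
        If communalities fail to stabilize within ``cfg.max_iter``.
    """
    R = corr.R
    p = R.shape[0]
    if cfg.k >= p:
        raise ExtractionError(f"k={cfg.k} must be smaller than the number of measures p={p}")

    h2 = _smc(R)
    Lambda = None
    for _ in range(cfg.max_iter):
        reduced = R.copy()
        np.fill_diagonal(reduced, h2)
        eigvals, eigvecs = np.linalg.eigh(reduced)
        top = np.argsort(eigvals)[::-1][: cfg.k]
        lam_k = eigvals[top]
        if lam_k[-1] <= 0:
            raise ExtractionError(
                f"eigenvalue {lam_k[-1]:.3e} <= 0 among the top {cfg.k}: "
                "insufficient factor structure for the requested k"
            )
        Lambda = eigvecs[:, top] * np.sqrt(lam_k)
        h2_new = np.clip((Lambda**2).sum(axis=1), 0.0, 1.0)
        delta = float(np.abs(h2_new - h2).max())
        h2 = h2_new
        if delta < cfg.tol:
            break
    else:
        raise ConvergenceError(
            f"communalities did not converge in {cfg.max_iter} iterations "
            f"(last change {delta:.3e})"
        )

    Lambda, Phi = _canonicalize(Lambda, np.eye(cfg.k))
    return FactorModel(
        k=cfg.k,
        Lambda=Lambda,
        h2=h2,
        Phi=Phi,
        measure_ids=corr.measure_ids,
        rotated=False,
    )


def _quartimin_criterion(L: np.ndarray) -> float:
    L2 = L**2
    k = L.shape[1]
    return float(np.sum(L2 * (L2 @ (np.ones((k, k)) - np.eye(k)))) / 4.0)


def _rotate_oblimin(A: np.ndarray, n_starts: int) -> tuple[np.ndarray, np.ndarray]:
    """Quartimin (oblimin, gamma=0) via GPA with random orthogonal restarts."""
    rng = np.random.default_rng(_ROTATION_SEED)
    k = A.shape[1]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for s in range(max(1, n_starts)):
        Q = np.eye(k) if s == 0 else ortho_group.rvs(k, random_state=rng)
        try:
            L, T = rotate_factors(A @ Q, "quartimin")
        except Exception:
            continue
        crit = _quartimin_criterion(L)
        if best is None or crit < best[0]:
            best = (crit, L, Q @ T)
    if best is None:
        raise ConvergenceError("oblimin rotation failed to converge from any start")
    _, L, T = best
    return L, T


def rotate(model: FactorModel, cfg: ExtractionConfig) -> FactorModel:
    """Apply the configured oblique rotation; update Lambda and Phi.

    The rotated Phi is preserved verbatim for the harmonizer — it is the
    constraint that equates latent factors across datasets. The fit is
    rotation-invariant: Lambda Phi Lambda' is unchanged.
    """
    if model.k == 1 or cfg.rotation == "none":
        L, Phi = _canonicalize(model.Lambda, np.eye(model.k))
        return replace(model, Lambda=L, Phi=Phi, rotated=True)

    if cfg.rotation == "oblimin":
        L, T = _rotate_oblimin(model.Lambda, cfg.n_rotation_starts)
    else:  # promax
        from statsmodels.multivariate.factor_rotation import promax as _promax

        L, T = _promax(model.Lambda)
    Phi = T.T @ T
    # enforce an exact correlation matrix against numerical drift
    d = np.sqrt(np.diag(Phi))
    Phi = Phi / np.outer(d, d)
    L = L * d  # compensate so Lambda Phi Lambda' is preserved
    L, Phi = _canonicalize(L, Phi)
    return replace(model, Lambda=L, Phi=Phi, rotated=True)


def score_weights(model: FactorModel, corr: CompositeCorrelation) -> FactorModel:
    """Thurstone regression score weights W = R^-1 Lambda Phi."""
    R = corr.R
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularMatrixError(
            f"correlation matrix is numerically singular (condition number {cond:.3e}); "
            "see the conditioning report"
        )
    W = np.linalg.solve(R, model.Lambda @ model.Phi)
    return replace(model, W=W)
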