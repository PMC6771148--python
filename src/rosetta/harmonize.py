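"""Apply the shared factor model to each constituent dataset and emit scores.

This is the harmonization step proper. The composite correlation matrix and
the factor correlation matrix Phi are shared by construction; each dataset
gets its own loading matrix with *structural zeros* in the rows of measures
it never observed, and its own regression score weights computed on the
composite submatrix of its available measures. Because every dataset's
weights derive from the same correlations and the same Phi, the resulting
per-subject factor scores are commensurate across datasets and can be
concatenated for a single mega-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .composite import (
    CompositeCorrelation,
    ConditioningReport,
    conditioning_report,
    nearest_psd,
    pairwise_correlation,
    require_well_conditioned,
)
from .datapool import DataPool, Dataset
from .errors import ExtractionError, ScoringError, SingularMatrixError, StageError
from .factors import ExtractionConfig, FactorModel, extract, rotate, score_weights

__all__ = [
    "DatasetModel",
    "HarmonizedScores",
    "Standardization",
    "pooled_standardization",
    "constrain_dataset",
    "score_dataset",
    "harmonize",
]

ConstraintMode = Literal["refit", "subset"]


@dataclass
class Standardization:
    """Per-measure centering/scaling statistics shared by all datasets.

    Means and SDs are pooled over every dataset observing each measure, so a
    given raw value maps to the same z-score regardless of which dataset it
    came from — a precondition for commensurate scores.
    """

    means: pd.Series
    sds: pd.Series

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        cols = values.columns
        return (values - self.means[cols]) / self.sds[cols]


def pooled_standardization(pool: DataPool) -> Standardization:
    big = pool.concat()
    means = big.mean(skipna=True)
    sds = big.std(skipna=True, ddof=1)
    flat = sds[(sds == 0) | sds.isna()].index.tolist()
    if flat:
        raise ScoringError(f"cannot standardize zero-variance measure(s): {flat}")
    return Standardization(means=means, sds=sds)


@dataclass
class DatasetModel:
    """The shared factor model restricted to one dataset.

    Rows of ``Lambda_d`` for measures the dataset never observed are exactly
    zero; ``Phi`` is identical to the composite model's factor correlation
    matrix — the constraint that makes factors equivalent across datasets.
    ``W_d`` has one row per available measure, aligned with ``available``.
    """

    dataset_id: str
    available: tuple[str, ...]
    Lambda_d: np.ndarray
    W_d: np.ndarray
    Phi: np.ndarray
    fit_discrepancy: float
    corr: CompositeCorrelation


@dataclass
class HarmonizedScores:
    """Concatenated per-subject factor scores (columns subject_id, dataset_id, D1..Dk).

    Carries the fitted composite objects for inspection; downstream analyses
    only need ``frame``.
    """

    frame: pd.DataFrame
    model: FactorModel | None = None
    corr: CompositeCorrelation | None = None
    dataset_models: list[DatasetModel] = field(default_factory=list)
    conditioning: ConditioningReport | None = None

    @property
    def factor_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("D")]

    def scores(self) -> pd.DataFrame:
        return self.frame.set_index("subject_id")[self.factor_columns]


def _sub_weights(corr: CompositeCorrelation, idx: np.ndarray, Lambda_rows: np.ndarray,
                 Phi: np.ndarray) -> np.ndarray:
    """Regression weights on the composite submatrix for measure subset idx."""
    R_ss = corr.submatrix(idx)
    cond = np.linalg.cond(R_ss)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularMatrixError(
            f"composite submatrix for measures {idx.tolist()} is numerically singular"
        )
    return np.linalg.solve(R_ss, Lambda_rows @ Phi)


def constrain_dataset(
    model: FactorModel,
    corr: CompositeCorrelation,
    dataset: Dataset,
    mode: ConstraintMode = "refit",
) -> DatasetModel:
    """Build the per-dataset model under the shared-correlation constraints.

    mode="refit" (default): re-estimate the available-measure loadings by a
    least-squares fit of Lambda_A Phi Lambda_A' + diag(uniqueness) to the
    composite correlation submatrix, with Phi held fixed, under the
    confirmatory pattern implied by the composite model (each measure loads
    only on its dominant composite factor; all cross-loadings are fixed
    zeros). The pattern makes the fit well-identified — a dense per-dataset
    loading matrix would be under-determined by the off-diagonal residuals
    alone. mode="subset": copy the composite loadings (including their small
    sample cross-loadings) verbatim. With correlations shared by
    construction the two coincide asymptotically; refit mirrors a
    constrained confirmatory fit per dataset.
    """
    ids = list(corr.measure_ids)
    avail = [m for m in ids if m in dataset.available]
    if not avail:
        raise ExtractionError(f"dataset {dataset.dataset_id!r} observes no catalog measures")
    idx = np.array([ids.index(m) for m in avail])
    k = model.k
    if len(avail) < k:
        raise ExtractionError(
            f"dataset {dataset.dataset_id!r} has {len(avail)} measures < k={k}"
        )

    R_aa = corr.submatrix(idx)
    Phi = model.Phi
    L0 = model.Lambda[idx]
    iu = np.triu_indices(len(avail), k=1)

    if mode == "refit":
        # confirmatory pattern from the composite model: one free loading per
        # measure, on its dominant factor; cross-loadings are structural zeros
        pattern = np.argmax(np.abs(model.Lambda), axis=1)[idx]
        rows = np.arange(len(avail))

        def make_L(x: np.ndarray) -> np.ndarray:
            L = np.zeros_like(L0)
            L[rows, pattern] = x
            return L

        def resid(x: np.ndarray) -> np.ndarray:
            L = make_L(x)
            return ((L @ Phi @ L.T) - R_aa)[iu]

        sol = least_squares(resid, L0[rows, pattern], xtol=1e-12, ftol=1e-12)
        L_a = make_L(sol.x)
        discrepancy = float(np.sum(sol.fun**2))
    elif mode == "subset":
        L_a = L0.copy()
        discrepancy = float(np.sum(((L_a @ Phi @ L_a.T) - R_aa)[iu] ** 2))
    else:
        raise ValueError(f"unknown constraint mode {mode!r}")

    W_d = _sub_weights(corr, idx, L_a, Phi)
    Lambda_d = np.zeros_like(model.Lambda)
    Lambda_d[idx] = L_a
    return DatasetModel(
        dataset_id=dataset.dataset_id,
        available=tuple(avail),
        Lambda_d=Lambda_d,
        W_d=W_d,
        Phi=Phi,
        fit_discrepancy=discrepancy,
        corr=corr,
    )


def score_dataset(
    dm: DatasetModel,
    dataset: Dataset,
    stats: Standardization | None = None,
) -> pd.DataFrame:
    """Score every subject of one dataset: z-scored measurements times W_d.

    Rows with individually missing cells are scored with weights recomputed
    on the composite submatrix of the measures that subject actually has
    (rather than zero-filling, which would bias scores toward the mean for
    datasets with more cell-level missingness).
    """
    if stats is None:
        stats = Standardization(
            means=dataset.values.mean(skipna=True),
            sds=dataset.values.std(skipna=True, ddof=1),
        )
    values = dataset.values[list(dm.available)]
    Z = stats.apply(values).to_numpy()
    k = dm.W_d.shape[1]
    n = Z.shape[0]
    out = np.empty((n, k))

    obs = ~np.isnan(Z)
    none_observed = ~obs.any(axis=1)
    if none_observed.any():
        bad = dataset.subjects[none_observed][0]
        raise ScoringError(
            f"subject {bad!r} in dataset {dm.dataset_id!r} observes no measures; cannot score"
        )

    ids = list(dm.corr.measure_ids)
    avail_idx = np.array([ids.index(m) for m in dm.available])
    full = obs.all(axis=1)
    if full.any():
        out[full] = Z[full] @ dm.W_d

    if not full.all():
        rest = np.where(~full)[0]
        patterns: dict[bytes, list[int]] = {}
        for i in rest:
            patterns.setdefault(obs[i].tobytes(), []).append(i)
        nz = dm.Lambda_d[avail_idx]  # loadings aligned with available columns
        for key, rows in patterns.items():
            pat = np.frombuffer(key, dtype=bool)
            sub = np.where(pat)[0]
            W_s = _sub_weights(dm.corr, avail_idx[sub], nz[sub], dm.Phi)
            out[np.ix_(rows, range(k))] = Z[np.ix_(rows, sub)] @ W_s

    frame = pd.DataFrame(out, columns=[f"D{j + 1}" for j in range(k)])
    frame.insert(0, "dataset_id", dm.dataset_id)
    frame.insert(0, "subject_id", dataset.subjects.to_numpy())
    return frame


def harmonize(
    pool: DataPool,
    cfg: ExtractionConfig,
    mode: ConstraintMode = "refit",
    stage_log: list[str] | None = None,
) -> HarmonizedScores:
    """Run the full pipeline on a pool and return concatenated factor scores.

    Stages: pairwise composite correlation -> PSD smoothing -> conditioning
    gate -> principal-axis extraction -> oblique rotation -> regression score
    weights -> per-dataset constrained models -> scoring -> concatenation.
    Errors are re-raised tagged with the stage that produced them.
    """
    log = stage_log if stage_log is not None else []

    def stage(name: str, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        log.append(name)
        return result

    corr = stage("composite_correlation", pairwise_correlation, pool)
    corr = stage("psd_smoothing", nearest_psd, corr)
    report = stage("conditioning", conditioning_report, corr, pool.catalog)
    stage("conditioning_gate", require_well_conditioned, report)
    model = stage("extraction", extract, corr, cfg)
    model = stage("rotation", rotate, model, cfg)
    model = stage("score_weights", score_weights, model, corr)
    stats = stage("standardization", pooled_standardization, pool)

    dataset_models: list[DatasetModel] = []
    frames: list[pd.DataFrame] = []
    for ds in pool.datasets:
        dm = stage(f"constrain[{ds.dataset_id}]", constrain_dataset, model, corr, ds, mode)
        dataset_models.append(dm)
        frames.append(stage(f"score[{ds.dataset_id}]", score_dataset, dm, ds, stats))

    cols = ["subject_id", "dataset_id"] + [f"D{j + 1}" for j in range(cfg.k)]
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=cols)
    )
    return HarmonizedScores(
        frame=frame,
        model=model,
        corr=corr,
        dataset_models=dataset_models,
        conditioning=report,
    )
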