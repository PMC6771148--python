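"""Data model and I/O for pools of row-disjoint datasets with partial measurement overlap.

A *pool* is a collection of independent cohort datasets (disjoint subjects)
whose columns only partially overlap. The :class:`MeasurementCatalog` fixes
the common measurement namespace and, crucially, the measure order: every
matrix downstream (correlations, loadings, weights) is indexed in catalog
order so that models from different runs are comparable.

Missing data appears at two levels:

* whole measures absent from a dataset (systematic missingness) — encoded by
  a column simply not being present;
* individually missing cells within a dataset — encoded as NaN / empty CSV
  fields, excluded pairwise during correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import PoolValidationError

__all__ = [
    "MeasurementCatalog",
    "Dataset",
    "DataPool",
    "read_catalog",
    "read_pool",
    "write_scores",
]


@dataclass(frozen=True)
class MeasurementCatalog:
    """Ordered namespace of measure identifiers, optionally tagged with domains.

    Parameters
    ----------
    measure_ids
        Unique measure names (e.g. ``V1`` … ``V9``); their order defines
        row/column order of every matrix in the pipeline.
    domain_of
        Optional map measure_id -> domain label. Domains are used by the
        simulator, conditioning diagnostics and reporting only; the core
        algorithm never reads them.
    """

    measure_ids: tuple[str, ...]
    domain_of: Mapping[str, str] | None = None

    def __post_init__(self):
        ids = tuple(str(m) for m in self.measure_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if list(ids).count(m) > 1})
            raise PoolValidationError(f"duplicate measure ids in catalog: {dupes}")
        if not ids:
            raise PoolValidationError("catalog is empty")
        object.__setattr__(self, "measure_ids", ids)
        if self.domain_of is not None:
            unknown = sorted(set(self.domain_of) - set(ids))
            if unknown:
                raise PoolValidationError(f"domain map refers to unknown measures: {unknown}")

    def __len__(self) -> int:
        return len(self.measure_ids)

    def index(self, measure_id: str) -> int:
        return self.measure_ids.index(measure_id)

    @property
    def domains(self) -> tuple[str, ...] | None:
        """Distinct domain labels in order of first appearance, or None."""
        if self.domain_of is None:
            return None
        seen: dict[str, None] = {}
        for m in self.measure_ids:
            d = self.domain_of.get(m)
            if d is not None:
                seen.setdefault(d, None)
        return tuple(seen)

    def measures_in_domain(self, domain: str) -> tuple[str, ...]:
        if self.domain_of is None:
            return ()
        return tuple(m for m in self.measure_ids if self.domain_of.get(m) == domain)


@dataclass
class Dataset:
    """One constituent dataset: subjects x available measures.

    ``values`` is indexed by subject id; its columns are the measures this
    dataset observed (a subset of the catalog). Cells may be NaN.
    """

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self):
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "subject_id"
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise PoolValidationError(
                f"dataset {self.dataset_id!r}: duplicate subject ids {dupes}"
            )

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def available(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class DataPool:
    """A validated collection of row-disjoint datasets under one catalog."""

    catalog: MeasurementCatalog
    datasets: list[Dataset] = field(default_factory=list)

    def __post_init__(self):
        known = set(self.catalog.measure_ids)
        seen_subjects: dict[str, str] = {}
        for ds in self.datasets:
            extra = [c for c in ds.available if c not in known]
            if extra:
                raise PoolValidationError(
                    f"dataset {ds.dataset_id!r}: columns not in catalog: {extra}"
                )
            # catalog order within each dataset, so sub-matrices align everywhere
            ordered = [m for m in self.catalog.measure_ids if m in ds.available]
            ds.values = ds.values[ordered]
            for s in ds.subjects:
                if s in seen_subjects:
                    raise PoolValidationError(
                        f"subject id {s!r} appears in both {seen_subjects[s]!r} "
                        f"and {ds.dataset_id!r}; pools must be row-disjoint"
                    )
                seen_subjects[s] = ds.dataset_id
        covered = set().union(*(set(ds.available) for ds in self.datasets)) if self.datasets else set()
        orphan = [m for m in self.catalog.measure_ids if m not in covered]
        if self.datasets and orphan:
            raise PoolValidationError(f"measures observed in no dataset: {orphan}")

    @property
    def n_total(self) -> int:
        return sum(ds.n for ds in self.datasets)

    def concat(self) -> pd.DataFrame:
        """All subjects x all catalog measures, NaN where unobserved."""
        if not self.datasets:
            return pd.DataFrame(columns=list(self.catalog.measure_ids))
        frames = [ds.values.reindex(columns=list(self.catalog.measure_ids)) for ds in self.datasets]
        return pd.concat(frames, axis=0)

    def dataset_of(self) -> pd.Series:
        """Series subject_id -> dataset_id in pool order."""
        parts = [
            pd.Series(ds.dataset_id, index=ds.subjects) for ds in self.datasets
        ]
        out = pd.concat(parts) if parts else pd.Series(dtype=object)
        out.index.name = "subject_id"
        return out


def read_catalog(path: str | Path) -> MeasurementCatalog:
    """Read a catalog CSV: either a flat one-column list of measure ids, or
    two columns ``measure_id,domain``. A header row is optional and detected
    by the literal column name ``measure_id``."""
    raw = pd.read_csv(path, header=None, dtype=str).dropna(how="all")
    if raw.empty:
        raise PoolValidationError(f"catalog file {path} is empty")
    if str(raw.iloc[0, 0]).strip().lower() == "measure_id":
        raw = raw.iloc[1:]
    ids = tuple(str(v).strip() for v in raw.iloc[:, 0])
    domain_of = None
    if raw.shape[1] >= 2 and raw.iloc[:, 1].notna().any():
        domain_of = {
            str(m).strip(): str(d).strip()
            for m, d in zip(raw.iloc[:, 0], raw.iloc[:, 1])
            if pd.notna(d)
        }
    return MeasurementCatalog(ids, domain_of)


def read_pool(paths: Sequence[str | Path], catalog_path: str | Path) -> DataPool:
    """Read constituent dataset CSVs (first column = subject id) into a pool.

    Each file contributes one dataset whose ``available`` set is exactly the
    columns present in that file. Validation errors name the offending file,
    column or subject id.
    """
    catalog = read_catalog(catalog_path)
    datasets = []
    for p in paths:
        p = Path(p)
        frame = pd.read_csv(p, index_col=0, float_precision="round_trip")
        frame.index = frame.index.astype(str)
        bad = [c for c in frame.columns if c not in catalog.measure_ids]
        if bad:
            raise PoolValidationError(f"file {p.name}: unknown columns {bad}")
        frame = frame.astype(float)
        datasets.append(Dataset(dataset_id=p.stem, values=frame))
    return DataPool(catalog=catalog, datasets=datasets)


def write_scores(scores, path: str | Path) -> None:
    """Write harmonized factor scores as CSV.

    Columns: ``subject_id, dataset_id, D1..Dk`` — one complete row per
    subject of every constituent dataset.
    """
    frame = scores.frame if hasattr(scores, "frame") else scores
    frame.to_csv(path, index=False)
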