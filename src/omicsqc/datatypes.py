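"""Core data types for omics quality evaluation.

The central object is :class:`OmicsDataTable`, a named feature-by-sample
numeric matrix with explicit missing values.  Every metric in the package
consumes one or more of these together with a :class:`SampleAnnotation`
collection and, for the biological-signal metrics, a
:class:`GeneSetCollection` of protein complexes or pathways.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


class OmicsQCError(ValueError):
    """Base class for all input-contract violations."""


class ParseError(OmicsQCError):
    """Malformed input file."""


class ValidationError(OmicsQCError):
    """Well-formed input that violates a data-model invariant."""


class Scale(str, enum.Enum):
    """Declared scale of a data table's values.

    ``raw`` means linear-scale intensities (non-negative); ``log2`` means the
    table is already log2-transformed.  The scale is declared by the user,
    never sniffed, because the two cannot be distinguished reliably from the
    values alone.
    """

    RAW = "raw"
    LOG2 = "log2"


@dataclass
class OmicsDataTable:
    """A named feature-by-sample quantification matrix.

    Parameters
    ----------
    name : str
        Short identifier used in reports and output file names.
    values : pandas.DataFrame
        Numeric matrix, features as rows (index = feature IDs), samples as
        columns.  Missing entries are NaN.
    scale : Scale or str
        Whether values are linear (``raw``) or log2-transformed.
    """

    name: str
    values: pd.DataFrame
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("table name must be non-empty")
        self.scale = Scale(self.scale)
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValidationError(
                f"table {self.name!r}: matrix must be non-empty, got shape {v.shape}"
            )
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"table {self.name!r}: duplicate feature IDs: {dups[:5]}"
            )
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(
                f"table {self.name!r}: duplicate sample IDs: {dups[:5]}"
            )
        try:
            self.values = v.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"table {self.name!r}: non-numeric values present: {exc}"
            ) from exc
        arr = self.values.to_numpy()
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            i, j = np.argwhere(~finite)[0]
            raise ValidationError(
                f"table {self.name!r}: non-finite value at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.scale is Scale.RAW:
            with np.errstate(invalid="ignore"):
                neg = arr < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise ValidationError(
                    f"table {self.name!r}: negative value on raw scale at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the entry is missing."""
        return self.values.isna()

    def identified_features(self) -> pd.Index:
        """Features with at least one non-missing value."""
        return self.values.index[self.values.notna().any(axis=1)]

    def to_linear(self, base: float = 2.0) -> pd.DataFrame:
        """Values on the linear scale (back-transforming log2 tables)."""
        if self.scale is Scale.LOG2:
            return base ** self.values
        return self.values

    def subset_samples(self, sample_ids: list[str]) -> "OmicsDataTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(
                f"table {self.name!r}: samples not present: {sorted(missing)}"
            )
        return OmicsDataTable(self.name, self.values.loc[:, list(sample_ids)], self.scale)


@dataclass
class SampleAnnotation:
    """Per-sample study metadata.

    Stored as a DataFrame indexed by sample ID with columns ``class_label``,
    ``batch`` (default a single level ``"B1"``), ``order`` (nullable integer
    run order) and ``is_qc`` (boolean QC-replicate flag, default False).
    """

    table: pd.DataFrame

    REQUIRED = ("class_label", "batch", "order", "is_qc")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in annotation: {dups[:5]}")
        if len(t) == 0:
            raise ValidationError("annotation must contain at least one sample")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if t["class_label"].isna().any():
            raise ValidationError("class_label must be present for every sample")
        # run order must be unique within each batch where given
        with_order = t[t["order"].notna()]
        for batch, grp in with_order.groupby("batch", observed=True):
            if grp["order"].duplicated().any():
                raise ValidationError(
                    f"duplicate run order values within batch {batch!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def class_labels(self) -> pd.Series:
        return self.table["class_label"]

    @property
    def batches(self) -> pd.Series:
        return self.table["batch"]

    @property
    def qc_samples(self) -> list[str]:
        return [str(s) for s in self.table.index[self.table["is_qc"].astype(bool)]]

    def subset(self, sample_ids: list[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(sample_ids)].copy())


class GeneSetKind(str, enum.Enum):
    COMPLEX = "complex"
    PATHWAY = "pathway"


@dataclass
class GeneSetCollection:
    """Named feature sets (protein complexes or pathways)."""

    kind: GeneSetKind
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.kind = GeneSetKind(self.kind)
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> set[str]:
        """Union of all set members."""
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def restrict(self, features: set[str]) -> "GeneSetCollection":
        """Keep only members present in *features*; drop emptied sets."""
        kept = {
            name: [m for m in members if m in features]
            for name, members in self.sets.items()
        }
        return GeneSetCollection(self.kind, {n: m for n, m in kept.items() if m})


@dataclass
class EvaluationConfig:
    """Tunable parameters of the evaluation pipeline.

    Attributes
    ----------
    quantifiable_min_fraction : float
        A feature is "quantifiable" if observed in at least this fraction of
        samples (default 0.5).
    cv_threshold : float
        CV cutoff for the reproducibility metric; the reported fraction is
        the share of QC-derived CVs below this value (default 0.30).
    rwr_restart : float
        Restart probability of the random walk with restart (default 0.5).
    rwr_tol : float
        L1 convergence tolerance of the RWR iteration (default 1e-6).
    network_top_k : int
        Each feature is connected to its top-k most correlated partners when
        building the co-expression network (default 10).
    n_pca_components : int
        Number of principal components computed for embedding, silhouette
        and PCR (default 10; capped at the matrix rank).
    pcr_variance_target : float
        PCR uses the leading components covering at least this fraction of
        variance (default 0.8), capped at ``pcr_max_components``.
    pcr_max_components : int
        Hard cap on components entering PCR (default 10).
    silhouette_components : int
        Number of leading PCs in which the batch silhouette is computed
        (default 2).
    cv_folds : int
        Cross-validation folds for function prediction and class prediction
        (default 5).
    n_complex_pairs : int
        Number of intra-complex (and inter-complex) feature pairs sampled
        for the correlation analysis (default 200).
    random_seed : int
        Seed for every stochastic step (pair sampling, fold assignment).
    class_column_for_ml : str
        Annotation column holding the two-level sample classification used
        by the supervised metrics (default ``class_label``).
    log_base_for_cv : float
        Base used to back-transform log-scale tables before computing CVs
        (default 2).
    min_complete_pairs : int
        Minimum pairwise-complete observations for a correlation to be
        reported (default 6).
    """

    quantifiable_min_fraction: float = 0.5
    cv_threshold: float = 0.30
    rwr_restart: float = 0.5
    rwr_tol: float = 1e-6
    network_top_k: int = 10
    n_pca_components: int = 10
    pcr_variance_target: float = 0.8
    pcr_max_components: int = 10
    silhouette_components: int = 2
    cv_folds: int = 5
    n_complex_pairs: int = 200
    random_seed: int = 42
    class_column_for_ml: str = "class_label"
    log_base_for_cv: float = 2.0
    min_complete_pairs: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.quantifiable_min_fraction <= 1:
            raise ValidationError("quantifiable_min_fraction must be in (0, 1]")
        if not 0 < self.cv_threshold:
            raise ValidationError("cv_threshold must be positive")
        if not 0 < self.rwr_restart < 1:
            raise ValidationError("rwr_restart must be in (0, 1)")
        if self.rwr_tol <= 0:
            raise ValidationError("rwr_tol must be positive")
        if self.network_top_k < 1:
            raise ValidationError("network_top_k must be >= 1")
        if self.n_pca_components < 1:
            raise ValidationError("n_pca_components must be >= 1")
        if not 0 < self.pcr_variance_target <= 1:
            raise ValidationError("pcr_variance_target must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.n_complex_pairs < 1:
            raise ValidationError("n_complex_pairs must be >= 1")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EvaluationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class MetricResult:
    """One named metric value attributed to one table and metric group.

    ``value`` is the scalar summary (may be None for purely tabular
    results); ``detail`` holds per-sample / per-feature vectors or matrices
    as pandas objects, keyed by a short name.
    """

    table_name: str
    group: str
    metric: str
    value: float | None
    detail: dict[str, Any] = field(default_factory=dict)
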