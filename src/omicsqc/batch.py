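"""Batch-effect quantification: silhouette width on a PCA embedding and
principal-component regression (PCR), plus the PCA coordinates and
sample-correlation matrices used for visualization.

Both scalar metrics are oriented so that *higher means more batch effect*:
the average silhouette width of the batch labels in PCA space, and the
variance-weighted R² of one-way ANOVAs of PC scores on the batch factor.
The report maps both to quality scores as ``1 − clamp(metric, 0, 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .datatypes import EvaluationConfig, OmicsDataTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PcaEmbedding:
    coords: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_fractions: np.ndarray  # per-component fraction of total variance


@dataclass
class BatchAssessment:
    table_name: str
    asw_batch: float  # in [-1, 1]
    pcr_batch_r2: float  # in [0, 1]
    pca: PcaEmbedding
    sample_correlation: pd.DataFrame


def pca_embed(table: OmicsDataTable, config: EvaluationConfig) -> PcaEmbedding:
    """Embed samples into PCA space.

    Features with missing values are median-imputed (embedding only — no
    other metric sees imputed values), zero-variance features dropped and
    features centered.  Component signs are fixed so the largest-magnitude
    loading of each component is positive, making coordinates deterministic.
    """
    if table.n_samples < 3:
        raise ValidationError(f"table {table.name!r}: PCA needs >= 3 samples")
    X = table.values.to_numpy(dtype=float)  # features x samples
    medians = np.nanmedian(X, axis=1)
    all_missing = np.isnan(medians)
    if all_missing.any():
        X = X[~all_missing]
    inds = np.where(np.isnan(X))
    if inds[0].size:
        X[inds] = np.take(np.nanmedian(X, axis=1), inds[0])
    var = X.var(axis=1)
    X = X[var > 0]
    if X.shape[0] == 0:
        raise ValidationError(f"table {table.name!r}: no usable (varying) features")
    Xs = X.T - X.mean(axis=1)  # samples x features, feature-centered
    k = min(config.n_pca_components, min(Xs.shape) - 1 if min(Xs.shape) > 1 else 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs)
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    coords = pd.DataFrame(
        scores,
        index=table.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaEmbedding(coords=coords, variance_fractions=pca.explained_variance_ratio_)


def average_silhouette_width(coords: pd.DataFrame | np.ndarray,
                             labels: pd.Series | np.ndarray) -> float:
    """Mean silhouette width s(i) = (b−a)/max(a,b) with Euclidean distance.

    Samples in singleton clusters contribute s(i) = 0.  Raises when the
    labels have a single level (the metric is undefined).
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    if len(np.unique(y)) < 2:
        raise ValidationError("silhouette needs >= 2 label levels")
    return float(np.mean(silhouette_samples(X, y, metric="euclidean")))


def principal_component_regression(
    embedding: PcaEmbedding,
    labels: pd.Series | np.ndarray,
    n_top: int | None = None,
    variance_target: float = 0.8,
    max_components: int = 10,
) -> float:
    """Variance-weighted batch R² over leading principal components.

    Per component the R² of a one-way ANOVA of scores on the batch factor
    (between-group SS / total SS) is computed; components are weighted by
    their variance fractions.  When ``n_top`` is None the leading components
    covering at least ``variance_target`` of the variance are used, capped
    at ``max_components``.  Zero-variance components are excluded.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("PCR needs >= 2 label levels")
    vf = np.asarray(embedding.variance_fractions, dtype=float)
    scores = embedding.coords.to_numpy(dtype=float)
    if n_top is None:
        cum = np.cumsum(vf) / max(vf.sum(), np.finfo(float).tiny)
        n_top = int(np.searchsorted(cum, variance_target) + 1)
        n_top = min(n_top, max_components)
    n_top = max(1, min(n_top, scores.shape[1]))
    num = 0.0
    den = 0.0
    for k in range(n_top):
        s = scores[:, k]
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        if ss_tot <= 0:
            continue
        ss_between = 0.0
        for level in np.unique(y):
            grp = s[y == level]
            ss_between += len(grp) * (grp.mean() - s.mean()) ** 2
        r2 = ss_between / ss_tot
        num += vf[k] * r2
        den += vf[k]
    if den == 0:
        return 0.0
    return float(num / den)


def sample_correlation_matrix(
    table: OmicsDataTable, min_complete: int = 3
) -> pd.DataFrame:
    """Pearson correlation between sample columns on pairwise-complete data.

    Pairs with fewer than *min_complete* shared observations get a missing
    entry with a warning.
    """
    if table.n_samples < 2:
        raise ValidationError(f"table {table.name!r}: need >= 2 samples")
    corr = table.values.corr(method="pearson", min_periods=min_complete)
    off_diag_nan = corr.isna().to_numpy()
    np.fill_diagonal(off_diag_nan, False)
    if off_diag_nan.any():
        n_bad = int(off_diag_nan.sum()) // 2
        logger.warning(
            "table %r: %d sample pair(s) with < %d complete features; "
            "correlation left missing", table.name, n_bad, min_complete,
        )
    return corr


def assess_batch_effect(
    table: OmicsDataTable,
    batches: pd.Series,
    config: EvaluationConfig,
) -> BatchAssessment:
    """Full Group-3 assessment for one table."""
    embedding = pca_embed(table, config)
    batch_vec = batches.loc[table.sample_ids]
    n_levels = batch_vec.nunique()
    if n_levels >= 2:
        k_sil = min(config.silhouette_components, embedding.coords.shape[1])
        asw = average_silhouette_width(
            embedding.coords.iloc[:, :k_sil], batch_vec
        )
        pcr = principal_component_regression(
            embedding,
            batch_vec,
            variance_target=config.pcr_variance_target,
            max_components=config.pcr_max_components,
        )
    else:
        logger.info(
            "table %r: single batch; silhouette/PCR not applicable, reported as 0",
            table.name,
        )
        asw, pcr = 0.0, 0.0
    corr = sample_correlation_matrix(table)
    return BatchAssessment(
        table_name=table.name,
        asw_batch=asw,
        pcr_batch_r2=pcr,
        pca=embedding,
        sample_correlation=corr,
    )
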