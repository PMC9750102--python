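"""Platform reproducibility (QC-replicate CVs) and paired-omics concordance.

The coefficient of variation is computed per feature over the replicated QC
samples on the *linear* scale (log2-declared tables are back-transformed
first), with the n−1 sample standard deviation; the headline metric is the
fraction of features with CV below the configured threshold (default 30%).

Cross-omics concordance uses Spearman correlation on pairwise-complete
observations: mRNA–protein relationships are monotone but not linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    EvaluationConfig,
    OmicsDataTable,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class CvResult:
    table_name: str
    per_feature_cv: pd.Series  # feature -> CV, defined features only
    fraction_below_threshold: float
    threshold: float
    n_excluded: int  # features with <= 1 QC observation or non-positive mean


def qc_cv(
    table: OmicsDataTable,
    annotation: SampleAnnotation,
    config: EvaluationConfig,
) -> CvResult:
    """Per-feature CV over replicated QC samples.

    Features with fewer than 2 QC observations or a non-positive mean are
    excluded (and counted); the reported fraction is taken over features
    with a defined CV.
    """
    qc = [s for s in annotation.qc_samples if s in table.sample_ids]
    if len(qc) < 2:
        raise ValidationError(
            f"table {table.name!r}: reproducibility assessment skipped — "
            f"needs >= 2 QC replicate samples, found {len(qc)}"
        )
    linear = table.to_linear(base=config.log_base_for_cv)
    sub = linear.loc[:, qc]
    n_obs = sub.notna().sum(axis=1)
    means = sub.mean(axis=1, skipna=True)
    sds = sub.std(axis=1, ddof=1, skipna=True)
    defined = (n_obs >= 2) & (means > 0)
    cv = (sds[defined] / means[defined]).astype(float)
    cv.index.name = "feature"
    cv.name = "cv"
    n_excluded = int((~defined).sum())
    if len(cv) == 0:
        raise ValidationError(
            f"table {table.name!r}: no feature has a defined QC CV"
        )
    frac = float((cv < config.cv_threshold).mean())
    return CvResult(
        table_name=table.name,
        per_feature_cv=cv,
        fraction_below_threshold=frac,
        threshold=config.cv_threshold,
        n_excluded=n_excluded,
    )


@dataclass
class ConcordanceResult:
    table_name: str
    genewise_r: pd.Series  # feature -> Spearman r across samples
    samplewise_r: pd.Series  # sample -> Spearman r across features
    median_genewise_r: float


def paired_omics_concordance(
    table: OmicsDataTable,
    paired: OmicsDataTable,
    min_features: int = 10,
    min_samples: int = 6,
    min_complete: int = 6,
) -> ConcordanceResult:
    """Gene-wise and sample-wise Spearman correlation with a paired table.

    Correlations are computed on shared features and samples; any
    feature/sample needs at least ``min_complete`` complete observation
    pairs for its r to be reported.  Symmetric in the two tables.
    """
    shared_features = [f for f in table.feature_ids if f in set(paired.feature_ids)]
    shared_samples = [s for s in table.sample_ids if s in set(paired.sample_ids)]
    if len(shared_features) < min_features or len(shared_samples) < min_samples:
        raise ValidationError(
            f"tables {table.name!r} and {paired.name!r} share "
            f"{len(shared_features)} features and {len(shared_samples)} samples; "
            f"need >= {min_features} and >= {min_samples}"
        )
    A = table.values.loc[shared_features, shared_samples].to_numpy(dtype=float)
    B = paired.values.loc[shared_features, shared_samples].to_numpy(dtype=float)

    def spearman_rows(X: np.ndarray, Y: np.ndarray, names: list[str]) -> pd.Series:
        out = {}
        for i, name in enumerate(names):
            x, y = X[i], Y[i]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_complete:
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            out[name] = float(stats.spearmanr(x[ok], y[ok]).statistic)
        return pd.Series(out, dtype=float)

    genewise = spearman_rows(A, B, shared_features)
    samplewise = spearman_rows(A.T, B.T, shared_samples)
    genewise.index.name = "feature"
    samplewise.index.name = "sample"
    if len(genewise) == 0:
        raise ValidationError(
            f"tables {table.name!r}/{paired.name!r}: no feature has "
            f">= {min_complete} complete observation pairs"
        )
    return ConcordanceResult(
        table_name=table.name,
        genewise_r=genewise.rename("spearman_r"),
        samplewise_r=samplewise.rename("spearman_r"),
        median_genewise_r=float(genewise.median()),
    )
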