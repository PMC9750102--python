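"""Data-depth metrics: identified/quantifiable features, cross-table
overlap and missing-value distributions.

A feature is *identified* when it has at least one non-missing value and
*quantifiable* when it is observed in at least ``quantifiable_min_fraction``
of the samples (default 50%) — an explicit, configurable reading of the
common proteomics convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EvaluationConfig, OmicsDataTable, ValidationError


@dataclass
class DepthSummary:
    table_name: str
    n_identified: int
    n_quantifiable: int
    per_sample_counts: pd.Series  # sample -> non-missing feature count
    missing_fraction_per_feature: pd.Series  # feature -> fraction missing

    def __post_init__(self) -> None:
        assert self.n_quantifiable <= self.n_identified
        assert (self.per_sample_counts <= self.n_identified).all()


def depth_summary(table: OmicsDataTable, config: EvaluationConfig) -> DepthSummary:
    """Summarize identified and quantifiable feature counts for one table."""
    observed = table.values.notna()
    n_obs_per_feature = observed.sum(axis=1)
    n_identified = int((n_obs_per_feature >= 1).sum())
    min_obs = config.quantifiable_min_fraction * table.n_samples
    n_quantifiable = int((n_obs_per_feature >= min_obs).sum())
    per_sample = observed.sum(axis=0).astype(int)
    per_sample.index.name = "sample"
    missing_frac = 1.0 - n_obs_per_feature / table.n_samples
    missing_frac.index.name = "feature"
    return DepthSummary(
        table_name=table.name,
        n_identified=n_identified,
        n_quantifiable=n_quantifiable,
        per_sample_counts=per_sample,
        missing_fraction_per_feature=missing_frac,
    )


def quantifiable_features(table: OmicsDataTable, config: EvaluationConfig) -> pd.Index:
    """Features observed in at least the configured fraction of samples."""
    n_obs = table.values.notna().sum(axis=1)
    return table.values.index[n_obs >= config.quantifiable_min_fraction * table.n_samples]


def feature_overlap_sets(tables: list[OmicsDataTable]) -> pd.DataFrame:
    """Exclusive-intersection (UpSet) counts of identified features.

    Returns one row per non-empty membership pattern with a boolean column
    per table and a ``count`` column; counts sum to the size of the union of
    identified feature sets.  Overlap is computed on identified features so
    all-missing placeholder rows do not inflate it.
    """
    if len(tables) < 2:
        raise ValidationError(
            "feature overlap needs >= 2 tables; use depth_summary for one table"
        )
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise ValidationError("table names must be unique for overlap analysis")
    sets = {t.name: set(t.identified_features()) for t in tables}
    union = set().union(*sets.values())
    patterns: dict[tuple[bool, ...], int] = {}
    for feat in union:
        key = tuple(feat in sets[n] for n in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = []
    for key, count in patterns.items():
        row = dict(zip(names, key))
        row["count"] = count
        rows.append(row)
    out = pd.DataFrame(rows, columns=[*names, "count"])
    # largest exclusive intersections first, ties broken by pattern degree
    out = out.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
    return out


def missing_value_histogram(table: OmicsDataTable, n_bins: int = 10) -> pd.DataFrame:
    """Histogram of per-feature missing fractions over [0, 1].

    Bins are right-closed, the first bin additionally left-closed, so fully
    observed features land in the first bin and all-missing features in the
    last; counts sum to the number of features.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    frac = 1.0 - table.values.notna().sum(axis=1) / table.n_samples
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed: (a, b]; first bin [0, b]
    idx = np.searchsorted(edges, frac.to_numpy(), side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
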