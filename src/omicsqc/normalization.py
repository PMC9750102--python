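"""Normalization assessment: per-sample abundance distributions and
pairwise distribution similarity via AUROC.

For an (unordered) pair of samples the AUROC is the probability that a
randomly drawn value from one sample exceeds a randomly drawn value from the
other, ties counted half — the Mann–Whitney construction, computed exactly
from tie-corrected rank sums rather than from a fitted classifier.  Two
samples with identical abundance distributions give AUROC 0.5; a clean
location shift pushes it towards 0 or 1.  The per-pair similarity is
``1 − 2·|AUROC − 0.5|`` (1 = indistinguishable, 0 = perfectly separable)
and a table's similarity score is the unweighted mean over sample pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsDataTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistributionSimilarity:
    table_name: str
    pairwise_auroc: pd.DataFrame  # samples x samples, diagonal 0.5
    similarity_score: float  # in [0, 1]
    per_sample_quartiles: pd.DataFrame  # columns Q1, median, Q3


def rank_auroc(x: np.ndarray, y: np.ndarray) -> float:
    """AUROC = P(Y > X) + 0.5·P(Y = X) from tie-aware rank statistics."""
    n_x, n_y = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    rank_sum_y = ranks[n_x:].sum()
    u_y = rank_sum_y - n_y * (n_y + 1) / 2.0
    return float(u_y / (n_x * n_y))


def pairwise_distribution_auroc(table: OmicsDataTable) -> DistributionSimilarity:
    """Score cross-sample distribution similarity for one table.

    Samples with fewer than 2 non-missing values are excluded with a
    warning; at least 2 usable samples are required.
    """
    values = {
        s: table.values[s].dropna().to_numpy() for s in table.sample_ids
    }
    usable = [s for s, v in values.items() if len(v) >= 2]
    dropped = sorted(set(table.sample_ids) - set(usable))
    if dropped:
        logger.warning(
            "table %r: samples with < 2 observations excluded from "
            "distribution similarity: %s", table.name, dropped,
        )
    if len(usable) < 2:
        raise ValidationError(
            f"table {table.name!r}: need >= 2 samples with >= 2 observations"
        )
    n = len(usable)
    auc = pd.DataFrame(0.5, index=usable, columns=usable, dtype=float)
    contributions = []
    for i, j in combinations(range(n), 2):
        si, sj = usable[i], usable[j]
        a = rank_auroc(values[si], values[sj])
        auc.iloc[i, j] = a
        auc.iloc[j, i] = 1.0 - a
        contributions.append(1.0 - 2.0 * abs(a - 0.5))
    quartiles = _quartiles(values, usable)
    return DistributionSimilarity(
        table_name=table.name,
        pairwise_auroc=auc,
        similarity_score=float(np.mean(contributions)),
        per_sample_quartiles=quartiles,
    )


def _quartiles(values: dict[str, np.ndarray], samples: list[str]) -> pd.DataFrame:
    rows = {
        s: np.quantile(values[s], [0.25, 0.5, 0.75]) for s in samples
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["Q1", "median", "Q3"])
    out.index.name = "sample"
    return out


def abundance_distribution_summary(
    table: OmicsDataTable, n_grid: int = 128
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample five-number summary plus histogram densities on a shared grid.

    Quantiles use linear interpolation between order statistics (the "type
    7" rule, numpy's default) so hand checks are reproducible.  The grid
    spans the global min/max of non-missing values.  Samples that are empty
    after missing removal are excluded with a warning.

    Returns
    -------
    (summary, density) : tuple of DataFrames
        ``summary`` has one row per sample with columns min, Q1, median,
        Q3, max, n; ``density`` has grid midpoints as index and one density
        column per sample (each integrating to 1 over the grid).
    """
    arrs = {}
    for s in table.sample_ids:
        v = table.values[s].dropna().to_numpy()
        if len(v) == 0:
            logger.warning(
                "table %r: sample %r has no observations; excluded", table.name, s
            )
            continue
        arrs[s] = v
    if not arrs:
        raise ValidationError(f"table {table.name!r}: no sample has observations")
    summary = pd.DataFrame.from_dict(
        {
            s: [v.min(), *np.quantile(v, [0.25, 0.5, 0.75]), v.max(), len(v)]
            for s, v in arrs.items()
        },
        orient="index",
        columns=["min", "Q1", "median", "Q3", "max", "n"],
    )
    summary.index.name = "sample"
    lo = min(v.min() for v in arrs.values())
    hi = max(v.max() for v in arrs.values())
    if hi == lo:
        hi = lo + 1.0  # degenerate constant table: arbitrary unit-width grid
    edges = np.linspace(lo, hi, n_grid + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dens = {}
    for s, v in arrs.items():
        counts, _ = np.histogram(v, bins=edges)
        dens[s] = counts / (len(v) * (edges[1] - edges[0]))
    density = pd.DataFrame(dens, index=pd.Index(mids, name="value"))
    return summary, density
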