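"""Biological-signal metrics.

Four complementary assessments of how much biology a table retains:

1. **Complex-pair correlations** — members of the same protein complex
   (CORUM-style sets) should co-express.  Equal numbers of intra-complex and
   inter-complex feature pairs are sampled, Pearson r computed per pair, and
   the two r distributions summarized by a separation AUROC (0.5 = no
   signal, 1 = intra pairs always more correlated).
2. **Network-based function prediction** — a co-expression network is built
   (top-k |r| neighbours, union-symmetrized), and for each pathway a random
   walk with restart seeded from training members ranks held-out members
   against non-members under cross-validation; performance is the pooled
   AUROC per pathway, summarized by the median over pathways.
3. **Class prediction** — an L2-regularized logistic model predicts the
   two-level sample classification under stratified cross-validation;
   pooled out-of-fold AUROC.
4. **Clustering concordance** — average-linkage hierarchical clustering on
   correlation distance, cut at the number of class levels, compared with
   the class and batch partitions by adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datatypes import (
    EvaluationConfig,
    GeneSetCollection,
    OmicsDataTable,
    SampleAnnotation,
    ValidationError,
)
from .depth import quantifiable_features
from .normalization import rank_auroc

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# complex-pair correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class ComplexCorrelationResult:
    table_name: str
    intra_correlations: np.ndarray
    inter_correlations: np.ndarray
    separation_auroc: float
    n_pairs: int


def _pairwise_complete_pearson(
    x: np.ndarray, y: np.ndarray, min_n: int
) -> float | None:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_n:
        return None
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def complex_pair_correlations(
    table: OmicsDataTable,
    complexes: GeneSetCollection,
    n_pairs: int = 200,
    seed: int = 0,
    min_complete: int = 6,
) -> ComplexCorrelationResult:
    """Sample intra- vs inter-complex feature pairs and score separation.

    An intra pair shares at least one complex; an inter pair has both
    members in the complex universe but shares none, so the null is matched
    on annotation coverage.  Pairs without ``min_complete`` shared
    observations or with a constant member are resampled where possible.
    """
    present = set(table.feature_ids)
    restricted = complexes.restrict(present)
    membership: dict[str, set[str]] = {}
    for cname, members in restricted.sets.items():
        if len(members) < 2:
            continue
        for m in members:
            membership.setdefault(m, set()).add(cname)
    universe = sorted(membership)
    if len(universe) < 2:
        raise ValidationError(
            f"table {table.name!r}: no complex has >= 2 members in the table"
        )
    rng = np.random.default_rng(seed)

    intra_candidates: set[tuple[str, str]] = set()
    for members in restricted.sets.values():
        ms = sorted(m for m in members if m in membership)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                intra_candidates.add((ms[i], ms[j]))
    intra_list = sorted(intra_candidates)
    if not intra_list:
        raise ValidationError(f"table {table.name!r}: no eligible intra-complex pair")

    values = table.values
    arr = {f: values.loc[f].to_numpy(dtype=float) for f in universe}

    def correlate(pairs: list[tuple[str, str]]) -> list[float]:
        out = []
        for a, b in pairs:
            r = _pairwise_complete_pearson(arr[a], arr[b], min_complete)
            if r is not None:
                out.append(r)
        return out

    if len(intra_list) > n_pairs:
        idx = rng.choice(len(intra_list), size=n_pairs, replace=False)
        intra_pairs = [intra_list[i] for i in idx]
    else:
        intra_pairs = intra_list
        logger.info(
            "table %r: only %d intra-complex pairs available (requested %d)",
            table.name, len(intra_list), n_pairs,
        )
    intra_r = correlate(intra_pairs)
    if not intra_r:
        raise ValidationError(
            f"table {table.name!r}: no intra-complex pair with enough complete data"
        )

    # inter pairs: rejection-sample from the universe until matched in count
    target = len(intra_r)
    inter_r: list[float] = []
    seen: set[tuple[str, str]] = set()
    max_draws = 200 * target
    draws = 0
    while len(inter_r) < target and draws < max_draws:
        draws += 1
        a, b = rng.choice(len(universe), size=2, replace=False)
        fa, fb = universe[a], universe[b]
        key = (fa, fb) if fa < fb else (fb, fa)
        if key in seen or membership[fa] & membership[fb]:
            continue
        seen.add(key)
        r = _pairwise_complete_pearson(arr[fa], arr[fb], min_complete)
        if r is not None:
            inter_r.append(r)
    if len(inter_r) < target:
        # trim intra to match |intra| = |inter|
        logger.warning(
            "table %r: only %d inter-complex pairs found; trimming intra set",
            table.name, len(inter_r),
        )
        intra_r = intra_r[: len(inter_r)]
    if not inter_r:
        raise ValidationError(f"table {table.name!r}: no eligible inter-complex pair")
    auroc = rank_auroc(np.asarray(inter_r), np.asarray(intra_r))
    return ComplexCorrelationResult(
        table_name=table.name,
        intra_correlations=np.asarray(intra_r),
        inter_correlations=np.asarray(inter_r),
        separation_auroc=auroc,
        n_pairs=len(intra_r),
    )


# ---------------------------------------------------------------------------
# co-expression network + random walk with restart
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    nodes: list[str]
    graph: nx.Graph
    construction: dict = field(default_factory=dict)

    def adjacency(self) -> pd.DataFrame:
        A = nx.to_pandas_adjacency(self.graph, nodelist=self.nodes, weight="weight")
        return A


def build_coexpression_network(
    table: OmicsDataTable, config: EvaluationConfig
) -> CoexpressionNetwork:
    """Top-k co-expression network on quantifiable features.

    Feature–feature Pearson |r| on pairwise-complete observations (pairs
    with fewer than ``min_complete_pairs`` shared samples excluded); each
    node is connected to its top-k highest-|r| partners and the edge set is
    symmetrized by union.  Edge weight = |r|.
    """
    if table.n_samples < 6:
        raise ValidationError(f"table {table.name!r}: network needs >= 6 samples")
    feats = quantifiable_features(table, config)
    sub = table.values.loc[feats]
    if len(feats) < 2:
        raise ValidationError(f"table {table.name!r}: < 2 quantifiable features")
    corr = sub.T.corr(method="pearson", min_periods=config.min_complete_pairs)
    A = corr.abs().to_numpy()
    np.fill_diagonal(A, np.nan)
    nodes = [str(f) for f in feats]
    k = config.network_top_k
    G = nx.Graph()
    G.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        row = A[i]
        valid = np.where(~np.isnan(row) & (row > 0))[0]
        if valid.size == 0:
            continue
        top = valid[np.argsort(row[valid], kind="stable")[::-1][:k]]
        for j in top:
            w = float(row[j])
            # union symmetrization: keep the edge if either endpoint selects it
            if G.has_edge(nodes[i], nodes[j]):
                G[nodes[i]][nodes[j]]["weight"] = max(G[nodes[i]][nodes[j]]["weight"], w)
            else:
                G.add_edge(nodes[i], nodes[j], weight=w)
    return CoexpressionNetwork(
        nodes=nodes,
        graph=G,
        construction={
            "correlation": "pearson_abs_pairwise_complete",
            "top_k": k,
            "weight": "abs_r",
        },
    )


def rwr_propagate(
    network: CoexpressionNetwork,
    seeds: set[str] | list[str],
    restart: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> pd.Series:
    """Random walk with restart over the weighted network.

    Iterates ``p ← (1−r)·M p + r·p₀`` where M is the column-normalized
    weighted adjacency and p₀ is uniform on the effective seed set; mass on
    zero-degree nodes is redistributed to p₀ so the vector stays a
    probability distribution.  Stops when the L1 change drops below *tol*
    or after *max_iter* iterations.
    """
    nodes = network.nodes
    idx = {f: i for i, f in enumerate(nodes)}
    eff = sorted(set(seeds) & set(nodes))
    if not eff:
        raise ValidationError("no seed feature is present in the network")
    n = len(nodes)
    A = nx.to_scipy_sparse_array(network.graph, nodelist=nodes, weight="weight", format="csr")
    colsum = np.asarray(A.sum(axis=0)).ravel()
    dangling = colsum == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, colsum))
    M = A.multiply(inv[np.newaxis, :]).tocsr()
    p0 = np.zeros(n)
    p0[[idx[s] for s in eff]] = 1.0 / len(eff)
    p = p0.copy()
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum()
        p_new = (1.0 - restart) * (M @ p + dangling_mass * p0) + restart * p0
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return pd.Series(p, index=nodes, name="rwr_score")


@dataclass
class FunctionPredictionResult:
    table_name: str
    per_pathway_auroc: dict[str, float]
    median_auroc: float | None


def function_prediction_auroc(
    network: CoexpressionNetwork,
    pathways: GeneSetCollection,
    config: EvaluationConfig,
    table_name: str = "",
) -> FunctionPredictionResult:
    """Cross-validated RWR pathway-membership prediction AUROC.

    A pathway is eligible when at least ``max(5, cv_folds)`` of its members
    are network nodes.  Its members are split into ``cv_folds`` folds
    (seeded); per fold the walk is seeded from the training members, and
    held-out members are ranked against all non-members.  Held-out and
    negative scores are pooled across folds into one tie-aware AUROC.
    """
    node_set = set(network.nodes)
    min_members = max(5, config.cv_folds)
    rng = np.random.default_rng(config.random_seed)
    per_pathway: dict[str, float] = {}
    for pname, members in pathways.sets.items():
        pos = sorted(set(members) & node_set)
        if len(pos) < min_members:
            logger.info(
                "pathway %r: %d network members < %d; excluded", pname, len(pos), min_members
            )
            continue
        neg = sorted(node_set - set(pos))
        if not neg:
            continue
        order = rng.permutation(len(pos))
        folds: list[list[str]] = [[] for _ in range(config.cv_folds)]
        for rank, i in enumerate(order):
            folds[rank % config.cv_folds].append(pos[i])
        pos_scores: list[float] = []
        neg_scores: list[float] = []
        for held_out in folds:
            train = sorted(set(pos) - set(held_out))
            if not train or not held_out:
                continue
            scores = rwr_propagate(
                network, train, restart=config.rwr_restart, tol=config.rwr_tol
            )
            pos_scores.extend(scores.loc[held_out].tolist())
            neg_scores.extend(scores.loc[neg].tolist())
        if pos_scores and neg_scores:
            per_pathway[pname] = rank_auroc(
                np.asarray(neg_scores), np.asarray(pos_scores)
            )
    if not per_pathway:
        logger.warning("no eligible pathway for function prediction")
        median = None
    else:
        median = float(np.median(list(per_pathway.values())))
    return FunctionPredictionResult(
        table_name=table_name, per_pathway_auroc=per_pathway, median_auroc=median
    )


# ---------------------------------------------------------------------------
# supervised class prediction
# ---------------------------------------------------------------------------

@dataclass
class ClassPredictionResult:
    table_name: str
    cv_auroc: float
    out_of_fold_scores: pd.Series  # sample -> score for the positive class


def class_prediction_cv_auroc(
    table: OmicsDataTable,
    annotation: SampleAnnotation,
    config: EvaluationConfig,
    n_top_features: int = 500,
) -> ClassPredictionResult:
    """Stratified CV AUROC of a regularized logistic model on the class labels.

    Features are the top ``n_top_features`` quantifiable features by
    variance; median imputation and standardization are fit inside each
    training fold.  Requires exactly two class levels, each with at least
    ``cv_folds`` samples.
    """
    labels = annotation.table.loc[table.sample_ids, config.class_column_for_ml]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"class prediction needs exactly 2 class levels, got {levels}"
        )
    counts = labels.value_counts()
    if (counts < config.cv_folds).any():
        raise ValidationError(
            f"each class needs >= {config.cv_folds} samples; got {counts.to_dict()}"
        )
    feats = quantifiable_features(table, config)
    if len(feats) == 0:
        raise ValidationError(f"table {table.name!r}: no quantifiable features")
    sub = table.values.loc[feats]
    variances = sub.var(axis=1, skipna=True).fillna(0.0)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_features]
    X = sub.loc[top].T.to_numpy(dtype=float)  # samples x features
    y = (labels == levels[1]).astype(int).to_numpy()
    model = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1.0, max_iter=2000)),
        ]
    )
    cv = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.random_seed
    )
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in cv.split(X, y):
        model.fit(X[train_idx], y[train_idx])
        oof[test_idx] = model.predict_proba(X[test_idx])[:, 1]
    assert not np.isnan(oof).any()
    auroc = rank_auroc(oof[y == 0], oof[y == 1])
    return ClassPredictionResult(
        table_name=table.name,
        cv_auroc=auroc,
        out_of_fold_scores=pd.Series(oof, index=table.sample_ids, name="score"),
    )


# ---------------------------------------------------------------------------
# unsupervised clustering concordance
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    table_name: str
    linkage_order: list[str]
    cluster_labels: pd.Series
    ari_vs_class: float
    ari_vs_batch: float


def clustering_concordance(
    table: OmicsDataTable, annotation: SampleAnnotation
) -> ClusteringResult:
    """Hierarchical clustering vs class and batch partitions.

    Distance 1 − Pearson r (pairwise-complete), average linkage, cut at
    k = number of class levels; concordance by adjusted Rand index.
    """
    if table.n_samples < 4:
        raise ValidationError(f"table {table.name!r}: clustering needs >= 4 samples")
    classes = annotation.table.loc[table.sample_ids, "class_label"]
    batches = annotation.table.loc[table.sample_ids, "batch"]
    k = classes.nunique()
    if k < 2:
        raise ValidationError("clustering concordance needs >= 2 class levels")
    corr = table.values.corr(method="pearson", min_periods=3)
    if corr.isna().to_numpy().any():
        raise ValidationError(
            f"table {table.name!r}: some sample pairs have < 3 complete features; "
            "filter shallow samples/features first"
        )
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    cluster_ids = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(cluster_ids, index=table.sample_ids, name="cluster")
    return ClusteringResult(
        table_name=table.name,
        linkage_order=[table.sample_ids[i] for i in leaves],
        cluster_labels=labels,
        ari_vs_class=float(adjusted_rand_score(classes, cluster_ids)),
        ari_vs_batch=float(adjusted_rand_score(batches, cluster_ids)),
    )
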