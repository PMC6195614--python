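"""Tumor response classification: gene–drug correlation, composite response
scoring, tercile thresholding, and PAM (k-medoids) cluster validation.

Two complementary routes label tumors sensitive / moderate / resistant:

* an explicit composite score — z(mean priming) minus z(mean log2 RQ over
  resistance genes) plus z(mean log2 RQ over protective genes) — cut at
  configurable (default tercile) thresholds, and
* unsupervised PAM clustering of z-scored Ct values concatenated with the
  per-drug priming percentages, with clusters mapped to labels by their
  mean priming (highest → sensitive, lowest → resistant).

PAM here is the classical Kaufman–Rousseeuw BUILD + SWAP algorithm with a
deterministic, lexicographic first-improvement swap order: no random
initialization, so results are reproducible by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .priming import PrimingMatrix
from .qpcr import CtTable, ExpressionTable
from .stats import pearson_r

AVERAGE_PRIMING = "average_priming"
LABELS = ("resistant", "moderate", "sensitive")


@dataclass
class CorrelationMatrix:
    """Gene × drug Pearson correlations with t-based two-tailed p-values.

    Columns include one pseudo-drug, ``average_priming`` (per-tumor mean
    priming over all drugs). Undefined correlations (constant input) are NaN.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stratum: str | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for gene in self.r.index:
            for drug in self.r.columns:
                rows.append(
                    {
                        "gene": gene,
                        "drug": drug,
                        "r": self.r.at[gene, drug],
                        "p": self.p.at[gene, drug],
                        "n": int(self.n.at[gene, drug]),
                        "stratum": self.stratum if self.stratum is not None else "all",
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class TumorClassification:
    """Per-tumor response labels from thresholding or PAM clustering."""

    labels: pd.Series                 # tumor -> {sensitive, moderate, resistant}
    score: pd.Series | None           # composite score (threshold route)
    method: str                       # "threshold" | "pam"
    medoids: tuple[str, ...] = ()     # pam only
    cluster_cost: float | None = None  # pam only: total within-cluster dissimilarity
    cluster_index: pd.Series | None = None  # pam only: raw cluster of each tumor
    extras: dict = field(default_factory=dict)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(list(LABELS), fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"label": self.labels})
        out["score"] = self.score if self.score is not None else np.nan
        out["method"] = self.method
        out.index.name = "sample_id"
        return out


def _align_tumors(expr: ExpressionTable, pm: PrimingMatrix) -> list[str]:
    shared = [s for s in pm.tumor_ids if s in expr.ddct.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 tumors shared between expression and priming")
    return shared


def gene_drug_correlation(
    expr: ExpressionTable,
    pm: PrimingMatrix,
    metadata: pd.DataFrame | None = None,
    group_by: str | None = None,
    genes: list[str] | None = None,
) -> CorrelationMatrix | dict[str, CorrelationMatrix]:
    """Pearson correlation of per-gene RQ against per-drug percent priming.

    For each (gene, drug) pair, r is computed across shared tumors between
    RQ(·, gene) and priming(·, drug); an extra column correlates against
    the per-tumor mean priming over all drugs. Significance is the exact
    two-tailed t transform, t = r·sqrt((n−2)/(1−r²)) on n−2 df. With
    ``group_by`` (a metadata column, e.g. ``gender``) one matrix per
    stratum is returned.
    """
    if group_by is not None:
        if metadata is None or group_by not in metadata.columns:
            raise KeyError(f"metadata column {group_by!r} required for stratification")
        out: dict[str, CorrelationMatrix] = {}
        for value in pd.unique(metadata[group_by].dropna()):
            keep = metadata.index[metadata[group_by] == value]
            sub = PrimingMatrix(
                priming=pm.priming.loc[pm.priming.index.intersection(keep)],
                replicate_cv=pm.replicate_cv.loc[pm.replicate_cv.index.intersection(keep)],
                clamped=pm.clamped.loc[pm.clamped.index.intersection(keep)],
                n_clamped=pm.n_clamped,
            )
            cm = gene_drug_correlation(expr, sub, genes=genes)
            assert isinstance(cm, CorrelationMatrix)
            cm.stratum = str(value)
            out[str(value)] = cm
        return out

    tumors = _align_tumors(expr, pm)
    genes = list(expr.gene_ids) if genes is None else list(genes)
    columns = list(pm.drug_ids) + [AVERAGE_PRIMING]
    prim = pm.priming.loc[tumors].copy()
    prim[AVERAGE_PRIMING] = prim[pm.drug_ids].mean(axis=1, skipna=True)
    r = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"), columns=columns)
    p = pd.DataFrame(np.nan, index=r.index, columns=columns)
    n = pd.DataFrame(0, index=r.index, columns=columns, dtype=int)
    for gene in genes:
        x = expr.rq.loc[tumors, gene].to_numpy(dtype=float)
        for col in columns:
            y = prim[col].to_numpy(dtype=float)
            ri, pi, ni = pearson_r(x, y)
            r.at[gene, col], p.at[gene, col], n.at[gene, col] = ri, pi, ni
    return CorrelationMatrix(r=r, p=p, n=n)


def tumor_response_score(
    expr: ExpressionTable,
    pm: PrimingMatrix,
    resistance_genes: list[str] | None = None,
    protective_genes: list[str] | None = None,
) -> pd.Series:
    """Composite per-tumor response score; higher = more drug-sensitive.

    score(i) = z(mean priming over drugs)
             − z(mean log2 RQ over resistance genes)
             + z(mean log2 RQ over protective genes)

    where z is cohort z-scoring (population SD; a constant term z-scores
    to 0 rather than dividing by zero). Defaults: protective = {TP53},
    resistance = all other genes in the expression table.
    """
    tumors = _align_tumors(expr, pm)
    if protective_genes is None:
        protective_genes = [g for g in expr.gene_ids if g == "TP53"]
    if resistance_genes is None:
        resistance_genes = [g for g in expr.gene_ids if g not in protective_genes]

    def z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd == 0.0:
            return pd.Series(0.0, index=v.index)
        return (v - v.mean()) / sd

    score = z(pm.priming.loc[tumors].mean(axis=1, skipna=True))
    log2rq = np.log2(expr.rq.loc[tumors])
    for sign, gene_set, name in (
        (-1.0, resistance_genes, "resistance"),
        (+1.0, protective_genes, "protective"),
    ):
        present = [g for g in gene_set if g in log2rq.columns]
        if not present:
            warnings.warn(f"empty {name} gene set; term omitted", stacklevel=2)
            continue
        score = score + sign * z(log2rq[present].mean(axis=1, skipna=True))
    return score.rename("score")


def classify_threshold(
    scores: pd.Series,
    cut_low: float | None = None,
    cut_high: float | None = None,
) -> TumorClassification:
    """Label tumors by score: < cut_low → resistant, ≥ cut_high → sensitive,
    else moderate. Default cuts are the cohort's score terciles; when the
    terciles coincide (degenerate score distribution) every tumor is
    moderate. Non-finite scores are excluded with a warning.
    """
    finite = scores[np.isfinite(scores)]
    if len(finite) < len(scores):
        warnings.warn(
            f"excluding {len(scores) - len(finite)} tumor(s) with non-finite scores",
            stacklevel=2,
        )
    defaulted = cut_low is None and cut_high is None
    if defaulted:
        cut_low, cut_high = np.quantile(finite.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    if cut_low is None or cut_high is None:
        raise ValueError("provide both cuts or neither")
    if not cut_low < cut_high:
        if defaulted:
            labels = pd.Series("moderate", index=finite.index, name="label")
            return TumorClassification(labels=labels, score=finite, method="threshold",
                                       extras={"cut_low": float(cut_low), "cut_high": float(cut_high)})
        raise ValueError("cut_low must be < cut_high")
    labels = pd.Series("moderate", index=finite.index, name="label")
    labels[finite < cut_low] = "resistant"
    labels[finite >= cut_high] = "sensitive"
    return TumorClassification(
        labels=labels,
        score=finite,
        method="threshold",
        extras={"cut_low": float(cut_low), "cut_high": float(cut_high)},
    )


class KMedoids:
    """Partitioning Around Medoids with deterministic BUILD + SWAP.

    BUILD greedily selects ``n_clusters`` medoids minimizing total
    dissimilarity; SWAP exchanges (medoid, non-medoid) pairs in
    lexicographic first-improvement order while any swap strictly lowers
    the total cost. Ties break toward the lowest point index, so fitting is
    fully deterministic.

    Follows the scikit-learn estimator protocol (``fit`` / ``predict``,
    fitted attributes with trailing underscores, ``get_params`` /
    ``set_params``) without depending on scikit-learn.

    Attributes (after ``fit``)
    --------------------------
    medoid_indices_ : ndarray of shape (n_clusters,)
    labels_ : ndarray of shape (n_samples,)
    inertia_ : float — total within-cluster dissimilarity to medoids
    n_swaps_ : int — accepted SWAP exchanges
    cluster_centers_ : ndarray — the medoid rows of X
    """

    def __init__(self, n_clusters: int = 3, metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.metric = metric

    # -- sklearn-style parameter plumbing -----------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "metric": self.metric}

    def set_params(self, **params) -> "KMedoids":
        for k, v in params.items():
            if k not in ("n_clusters", "metric"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -------------------------------------------------------------
    def _distances(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)
            if D.shape[0] != D.shape[1]:
                raise ValueError("precomputed distance matrix must be square")
            return D
        return cdist(X, X, metric=self.metric)

    def fit(self, X, y=None) -> "KMedoids":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        k = int(self.n_clusters)
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        n_distinct = (
            X.shape[0] if self.metric == "precomputed"
            else np.unique(X, axis=0).shape[0]
        )
        if k > n_distinct:
            raise ValueError(
                f"n_clusters={k} exceeds the number of distinct points ({n_distinct})"
            )
        D = self._distances(X)
        n = D.shape[0]

        # BUILD: greedy medoid selection minimizing total cost at each step
        medoids: list[int] = []
        nearest = np.full(n, np.inf)
        for _ in range(k):
            best_c, best_cost = -1, np.inf
            for c in range(n):
                if c in medoids:
                    continue
                cost = float(np.minimum(nearest, D[:, c]).sum())
                if cost < best_cost - 1e-12:
                    best_c, best_cost = c, cost
            medoids.append(best_c)
            nearest = np.minimum(nearest, D[:, best_c])

        # SWAP: lexicographic first-improvement until no swap lowers the cost
        def total_cost(meds: list[int]) -> float:
            return float(D[:, meds].min(axis=1).sum())

        cost = total_cost(medoids)
        n_swaps = 0
        improved = True
        while improved:
            improved = False
            for mi, m in enumerate(sorted(medoids)):
                pos = medoids.index(m)
                for h in range(n):
                    if h in medoids:
                        continue
                    trial = medoids.copy()
                    trial[pos] = h
                    c = total_cost(trial)
                    if c < cost - 1e-12:
                        medoids, cost = trial, c
                        n_swaps += 1
                        improved = True
                        break
                if improved:
                    break

        medoids_arr = np.array(sorted(medoids))
        labels = np.argmin(D[:, medoids_arr], axis=1)
        self.medoid_indices_ = medoids_arr
        self.labels_ = labels
        self.inertia_ = float(D[np.arange(n), medoids_arr[labels]].sum())
        self.n_swaps_ = n_swaps
        if self.metric != "precomputed":
            self.cluster_centers_ = X[medoids_arr]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "medoid_indices_"):
            raise RuntimeError("KMedoids instance is not fitted")
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)[:, self.medoid_indices_]
        else:
            D = cdist(np.asarray(X, dtype=float), self.cluster_centers_, metric=self.metric)
        return np.argmin(D, axis=1)


def pam_features(ct: CtTable, pm: PrimingMatrix) -> pd.DataFrame:
    """Tumor × feature matrix for PAM: z-scored Ct values of every target
    gene (columns ``ct:<gene>``) concatenated with z-scored per-drug percent
    priming (columns ``priming:<drug>``). Column-wise z-scoring puts cycles
    and percentage points on a common scale."""
    tumors = [t for t in pm.tumor_ids if t in ct.ct.index]
    blocks = {}
    for g in ct.target_genes:
        blocks[f"ct:{g}"] = ct.ct.loc[tumors, g]
    for d in pm.drug_ids:
        blocks[f"priming:{d}"] = pm.priming.loc[tumors, d]
    feats = pd.DataFrame(blocks, index=pd.Index(tumors, name="sample_id"))
    sd = feats.std(ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (feats - feats.mean()) / sd


def pam_cluster(
    features: pd.DataFrame,
    k: int = 3,
    metric: str = "euclidean",
    priming_columns: list[str] | None = None,
) -> TumorClassification:
    """Cluster tumors with PAM and map clusters to response labels.

    Clusters are ranked by their mean value over ``priming_columns``
    (default: every column named ``priming:<drug>``; falling back to all
    columns): the highest-priming cluster is sensitive, the lowest is
    resistant. For k ≠ 3, labels are ``cluster_0`` (lowest priming)
    through ``cluster_{k-1}`` (highest).
    """
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values; PAM needs complete rows")
    km = KMedoids(n_clusters=k, metric=metric).fit(X)
    tumors = list(features.index)
    cluster = pd.Series(km.labels_, index=tumors, name="cluster")
    if priming_columns is None:
        priming_columns = [c for c in features.columns if str(c).startswith("priming:")]
        if not priming_columns:
            priming_columns = list(features.columns)
    cluster_prime = (
        features[priming_columns].mean(axis=1).groupby(cluster).mean().sort_values()
    )
    if k == 3:
        name_by_rank = dict(zip(cluster_prime.index, LABELS))
    else:
        name_by_rank = {c: f"cluster_{i}" for i, c in enumerate(cluster_prime.index)}
    labels = cluster.map(name_by_rank).rename("label")
    return TumorClassification(
        labels=labels,
        score=None,
        method="pam",
        medoids=tuple(tumors[i] for i in km.medoid_indices_),
        cluster_cost=km.inertia_,
        cluster_index=cluster,
        extras={"n_swaps": km.n_swaps_, "k": k, "metric": metric},
    )
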