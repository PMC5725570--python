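"""Two-stage marker-driven cell-type classification of single cells.

Pipeline per stage: PCA + Barnes-Hut t-SNE embedding, DBSCAN density
clustering on the map, AND/OR/NOT marker scoring per cell, cluster-level
predominance labelling (>75% of the cluster's maximal total score, and only
if a single type passes) to obtain a sparse training set, a decision-tree
classifier over the classification gene set, and a 0.99-posterior "unknown"
rule. Stage two repeats the identical pipeline on the T-cell subset with a
slightly larger DBSCAN radius (1.75 instead of 1.5), reflecting the lower
density of the subset map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .containers import LOG2, ExpressionMatrix, MarkerSpec, ScaleError

UNKNOWN = "unknown"
NOISE = -1


@dataclass
class ClassifyParams:
    """Knobs of one classification stage; defaults follow the pipeline above."""

    eps: float = 1.5
    min_pts: int = 25
    perplexity: float = 30.0
    pca_dims: int = 50
    predominance: float = 0.75
    posterior_threshold: float = 0.99
    seed: int = 0


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # cell_id -> cluster id, -1 for noise
    embedding: pd.DataFrame           # cell_id x (x, y)

    def __post_init__(self):
        ids = sorted(set(self.labels) - {NOISE})
        if ids and ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0 (noise = -1)")


def _cells_matrix(m: ExpressionMatrix) -> np.ndarray:
    if m.scale != LOG2:
        raise ScaleError("classification expects log2-normalized data")
    return m.values.to_numpy().T  # cells x genes


def embed_tsne(
    m: ExpressionMatrix, pca_dims: int = 50, perplexity: float = 30.0, seed: int = 0,
) -> pd.DataFrame:
    """2-D Barnes-Hut t-SNE of cells, after PCA pre-reduction."""
    X = _cells_matrix(m)
    n_cells = X.shape[0]
    if n_cells < 2 * perplexity + 2:
        raise ValueError(
            f"{n_cells} cells is too few for perplexity {perplexity}; "
            "reduce the perplexity")
    dims = min(pca_dims, n_cells - 1, X.shape[1])
    if dims < X.shape[1]:
        X = PCA(n_components=dims, random_state=seed).fit_transform(X)
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca", method="barnes_hut").fit_transform(X)
    return pd.DataFrame(emb, index=m.column_ids, columns=["x", "y"])


def cluster_dbscan(embedding: pd.DataFrame, min_pts: int = 25, eps: float = 1.5) -> ClusterAssignment:
    """Euclidean DBSCAN on the 2-D map; sparse-region cells become noise."""
    coords = embedding.to_numpy()
    if not np.isfinite(coords).all():
        raise ValueError("embedding contains non-finite coordinates")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    return ClusterAssignment(pd.Series(labels, index=embedding.index), embedding)


def score_markers(m: ExpressionMatrix, spec: MarkerSpec) -> pd.DataFrame:
    """Cells x types marker score in [0, ...), higher = more type-like.

    Each marker gene is min-max normalized to [0, 1] across cells. Per cell
    and type the score is mean(normalized AND genes), gated to zero unless
    every AND gene is expressed, plus max(normalized OR genes), minus
    mean(normalized NOT genes), floored at zero.
    """
    spec = spec.restrict_to(m.gene_ids)
    vals = m.values
    norm = {}
    for g in spec.genes():
        row = vals.loc[g]
        span = row.max() - row.min()
        norm[g] = (row - row.min()) / span if span > 0 else row * 0.0
    scores = {}
    for ctype, lists in spec.markers.items():
        if not lists["AND"] and not lists["OR"]:
            raise ValueError(f"type {ctype!r} has neither AND nor OR marker genes")
        n_cells = vals.shape[1]
        if lists["AND"]:
            and_norm = pd.DataFrame({g: norm[g] for g in lists["AND"]})
            gate = (vals.loc[lists["AND"]] > 0).all(axis=0)
            and_term = and_norm.mean(axis=1) * gate
        else:
            and_term = pd.Series(0.0, index=vals.columns)
        or_term = (pd.DataFrame({g: norm[g] for g in lists["OR"]}).max(axis=1)
                   if lists["OR"] else pd.Series(0.0, index=vals.columns))
        not_term = (pd.DataFrame({g: norm[g] for g in lists["NOT"]}).mean(axis=1)
                    if lists["NOT"] else pd.Series(0.0, index=vals.columns))
        scores[ctype] = np.clip(and_term + or_term - not_term, 0, None)
    return pd.DataFrame(scores)


def label_clusters(
    scores: pd.DataFrame, clusters: ClusterAssignment, predominance: float = 0.75,
) -> pd.Series:
    """Sparse training labels from cluster-level total marker scores.

    Within each cluster the per-type scores are summed; types exceeding
    ``predominance`` of the maximal total "pass", and the cluster is labelled
    only when exactly one type passes — ambiguous clusters (e.g. NK vs T)
    stay unlabelled, as do noise cells.
    """
    if not scores.index.equals(clusters.labels.index):
        scores = scores.loc[clusters.labels.index]
    labels = pd.Series([None] * len(scores), index=scores.index, dtype=object)
    for cid, members in clusters.labels.groupby(clusters.labels).groups.items():
        if cid == NOISE:
            continue
        totals = scores.loc[members].sum(axis=0)
        smax = totals.max()
        if smax <= 0:
            continue
        passing = totals.index[totals > predominance * smax]
        if len(passing) == 1:
            labels.loc[members] = passing[0]
    return labels


@dataclass
class TrainedClassifier:
    model: DecisionTreeClassifier
    classes: list[str]
    gene_ids: list[str]
    posterior_threshold: float = 0.99

    def posteriors(self, m: ExpressionMatrix) -> pd.DataFrame:
        missing = [g for g in self.gene_ids if g not in m.gene_ids]
        if missing:
            raise ValueError(f"matrix lacks classifier genes: {missing[:10]}")
        X = m.values.loc[self.gene_ids].to_numpy().T
        if X.shape[0] == 0:
            return pd.DataFrame(columns=self.classes)
        proba = self.model.predict_proba(X)
        return pd.DataFrame(proba, index=m.column_ids, columns=self.model.classes_)


def train_classifier(
    m: ExpressionMatrix, labels: pd.Series, seed: int = 0,
    posterior_threshold: float = 0.99,
) -> TrainedClassifier:
    """Fit a decision tree on the labelled subset of cells.

    Posteriors are leaf class fractions of the (unpruned, Gini) tree.
    """
    labelled = labels.dropna()
    classes = sorted(set(labelled))
    if len(classes) < 2:
        raise ValueError("training requires at least two labelled classes")
    X = m.values[labelled.index].to_numpy().T
    model = DecisionTreeClassifier(random_state=seed)
    model.fit(X, labelled.to_numpy())
    return TrainedClassifier(model, classes, list(m.gene_ids), posterior_threshold)


def classify_cells(clf: TrainedClassifier, m: ExpressionMatrix) -> pd.Series:
    """Predicted type per cell; max posterior below the threshold -> "unknown"."""
    post = clf.posteriors(m)
    if post.empty:
        return pd.Series(dtype=object)
    best = post.idxmax(axis=1)
    conf = post.max(axis=1)
    return best.where(conf >= clf.posterior_threshold, UNKNOWN).astype(object)


def cross_validate(m: ExpressionMatrix, labels: pd.Series, k: int = 5, seed: int = 0) -> float:
    """Stratified k-fold mean accuracy of the decision tree on labelled cells."""
    labelled = labels.dropna()
    counts = labelled.value_counts()
    if len(counts) < 2:
        raise ValueError("cross-validation requires at least two classes")
    if (counts < k).any():
        small = counts.index[counts < k]
        raise ValueError(f"class(es) smaller than k={k}: {list(small)}")
    X = m.values[labelled.index].to_numpy().T
    y = labelled.to_numpy()
    accs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        model = DecisionTreeClassifier(random_state=seed)
        model.fit(X[train_idx], y[train_idx])
        accs.append(accuracy_score(y[test_idx], model.predict(X[test_idx])))
    return float(np.mean(accs))


@dataclass
class StageResult:
    annotation: pd.Series             # cell_id -> predicted type / "unknown"
    clusters: ClusterAssignment
    training_labels: pd.Series
    classifier: TrainedClassifier
    cv_accuracy: float


def classify_stage(
    m: ExpressionMatrix, spec: MarkerSpec, params: ClassifyParams,
    gene_set: list[str] | None = None,
) -> StageResult:
    """One full embed -> cluster -> score -> label -> train -> predict stage."""
    from .preprocess import filter_to_gene_set

    work = filter_to_gene_set(m, gene_set) if gene_set else m
    emb = embed_tsne(work, pca_dims=params.pca_dims, perplexity=params.perplexity,
                     seed=params.seed)
    clusters = cluster_dbscan(emb, min_pts=params.min_pts, eps=params.eps)
    scores = score_markers(work, spec)
    training = label_clusters(scores, clusters, predominance=params.predominance)
    clf = train_classifier(work, training, seed=params.seed,
                           posterior_threshold=params.posterior_threshold)
    annotation = classify_cells(clf, work)
    cv = cross_validate(work, training, k=5, seed=params.seed)
    return StageResult(annotation, clusters, training, clf, cv)


def classify_two_stage(
    m: ExpressionMatrix,
    spec_major: MarkerSpec,
    spec_tsub: MarkerSpec,
    params: ClassifyParams | None = None,
    t_label: str = "T cell",
    eps_stage2: float = 1.75,
    gene_set: list[str] | None = None,
) -> tuple[pd.Series, StageResult, StageResult | None]:
    """Major-type classification, then T-subset refinement on the T cells.

    Returns the merged annotation plus both stage results. Cells whose
    subset posterior stays below the threshold keep the major label
    ``t_label``; if no T cells are found the second stage is skipped.
    """
    params = params or ClassifyParams()
    stage1 = classify_stage(m, spec_major, params, gene_set=gene_set)
    annotation = stage1.annotation.copy()
    t_cells = annotation.index[annotation == t_label]
    if len(t_cells) == 0:
        warnings.warn("no T cells found; skipping subset classification", stacklevel=2)
        return annotation, stage1, None
    sub_m = ExpressionMatrix(m.values[t_cells], m.scale)
    sub_params = replace(params, eps=eps_stage2)
    try:
        stage2 = classify_stage(sub_m, spec_tsub, sub_params, gene_set=gene_set)
    except ValueError as err:
        warnings.warn(f"T-subset stage failed ({err}); keeping major labels",
                      stacklevel=2)
        return annotation, stage1, None
    refined = stage2.annotation.replace({UNKNOWN: t_label})
    annotation.loc[refined.index] = refined
    return annotation, stage1, stage2
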