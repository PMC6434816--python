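"""Time-course profiling of the adjusted biomineralization gene panel.

Three views of the adjusted expression matrix:

* PCA of samples over the panel genes — separates the early wound-healing
  phase (cell–48 h) from the late pearl-sac phase (1 w–3 m),
* agglomerative clustering of gene trajectories into expression groups
  (default four, labelled A–D in dendrogram order),
* per-gene trajectory export (mean adjusted TPM per time point) for
  plotting.

Both multivariate views work on log10(TPM + 1): genes are mean-centered
for PCA and z-scored for clustering, the field-standard transformations
for expression heatmaps and ordinations. Clustering uses correlation
distance with average linkage by default; both are configurable since
trajectory shape, not magnitude, defines the groups.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design import time_point_sort_key, TIME_POINTS
from .errors import EstimationError, MetadataError, SelectionError

logger = logging.getLogger(__name__)

LAYER_CLASSES = ("prismatic", "nacreous", "both", "other")


@dataclass
class ClusterAssignment:
    """Gene → group labels from one dendrogram cut."""

    labels: pd.Series  # index gene_id, values group letters
    linkage_matrix: np.ndarray
    n_groups: int
    leaf_order: list[str]


def load_gene_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "layer_class"} <= set(panel.columns):
        raise SelectionError(
            "gene panel table must have columns gene_id, layer_class"
        )
    bad = set(panel["layer_class"]) - set(LAYER_CLASSES)
    if bad:
        raise SelectionError(f"unknown layer_class values: {sorted(bad)}")
    if panel["gene_id"].duplicated().any():
        raise SelectionError("duplicate gene ids in panel")
    return panel


def select_panel(matrix: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Row-subset the expression matrix to the panel genes, in panel order.

    Panel genes absent from the matrix are reported (and listed in
    ``result.attrs["missing_genes"]``), never silently dropped. Zero
    overlap raises.
    """
    if len(panel) == 0:
        raise SelectionError("gene panel is empty")
    present = [g for g in panel["gene_id"] if g in matrix.index]
    missing = [g for g in panel["gene_id"] if g not in matrix.index]
    if not present:
        raise SelectionError("no panel gene found in the expression matrix")
    if missing:
        logger.warning(
            "%d panel gene(s) absent from the expression matrix: %s",
            len(missing), missing[:10],
        )
    out = matrix.loc[present].copy()
    out.attrs["missing_genes"] = missing
    return out


def _log_matrix(matrix: pd.DataFrame) -> np.ndarray:
    return np.log10(matrix.to_numpy(dtype=float) + 1.0)


def pca_profiles(
    matrix: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first two principal components.

    Rows of ``matrix`` are genes, columns samples; the PCA treats samples
    as observations and (log-transformed, mean-centered) genes as
    features. The sign of each component is fixed so its largest-magnitude
    gene loading is positive, making scores reproducible across libraries.

    Returns ``(scores, explained_variance_ratio)`` with scores indexed by
    sample id (columns PC1, PC2 — or just PC1 in the rank-1 case).
    """
    from sklearn.decomposition import PCA

    if matrix.shape[1] < 3:
        raise EstimationError("PCA needs at least 3 samples")
    if matrix.shape[0] < 1:
        raise EstimationError("PCA needs at least 1 gene")
    X = _log_matrix(matrix).T if log_transform else matrix.to_numpy(float).T
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise EstimationError(
            "expression matrix has no variance across samples; PCA undefined"
        )
    n_comp = min(2, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| gene positive per component
    for k in range(n_comp):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1.0
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def cluster_genes(
    matrix: pd.DataFrame,
    n_groups: int = 4,
    metric: str = "correlation",
    method: str = "average",
) -> ClusterAssignment:
    """Hierarchically cluster gene trajectories into ``n_groups`` groups.

    Gene rows are log10(TPM+1)-transformed and z-scored (constant rows get
    a zero profile) before computing pairwise distances; the dendrogram is
    cut with scipy's ``maxclust`` criterion. Groups are lettered A, B, …
    by their first appearance in dendrogram leaf order, matching how
    heatmap group labels read left to right.
    """
    if n_groups > matrix.shape[0]:
        raise EstimationError(
            f"n_groups={n_groups} exceeds gene count {matrix.shape[0]}"
        )
    X = _log_matrix(matrix)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant trajectories become zero profiles
    Z = (X - mu) / sd
    if metric == "correlation":
        # correlation distance is undefined for constant (zero) rows; give
        # them a tiny deterministic tilt so they cluster together
        flat = np.where(np.ptp(Z, axis=1) == 0)[0]
        if flat.size:
            Z[flat, 0] += 1e-9
    dist = pdist(Z, metric=metric)
    link = hierarchy.linkage(dist, method=method)
    raw = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    leaves = hierarchy.leaves_list(link)
    seen: dict[int, str] = {}
    letters = string.ascii_uppercase
    for leaf in leaves:
        c = raw[leaf]
        if c not in seen:
            idx = len(seen)
            seen[c] = (
                letters[idx] if idx < 26 else f"G{idx + 1}"
            )
    labels = pd.Series(
        [seen[c] for c in raw], index=matrix.index, name="group"
    )
    return ClusterAssignment(
        labels=labels,
        linkage_matrix=link,
        n_groups=int(labels.nunique()),
        leaf_order=[matrix.index[i] for i in leaves],
    )


def export_trajectories(
    matrix: pd.DataFrame,
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene time-course table: mean adjusted TPM over replicates.

    Long format: gene_id, layer_class, time_point, mean_tpm, n_replicates.
    Time points are ordered along the grafting course. A time point with
    fewer replicates than the design's maximum is still averaged over what
    is present; ``n_replicates`` exposes it.
    """
    meta = metadata.set_index("sample_id")
    unknown_samples = [s for s in matrix.columns if s not in meta.index]
    if unknown_samples:
        raise MetadataError(
            f"expression samples missing from metadata: {unknown_samples}"
        )
    tps = meta.loc[list(matrix.columns), "time_point"]
    bad = set(tps) - set(TIME_POINTS)
    if bad:
        raise MetadataError(f"unknown time point labels: {sorted(bad)}")

    layer = panel.set_index("gene_id")["layer_class"]
    sub = select_panel(matrix, panel)
    rows = []
    for tp in sorted(set(tps), key=time_point_sort_key):
        cols = [s for s in matrix.columns if tps[s] == tp]
        means = sub[cols].mean(axis=1)
        for gene, m in means.items():
            rows.append(
                dict(
                    gene_id=gene,
                    layer_class=layer[gene],
                    time_point=tp,
                    mean_tpm=float(m),
                    n_replicates=len(cols),
                )
            )
    return pd.DataFrame(rows)
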