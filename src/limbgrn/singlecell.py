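"""Single-cell co-expression stage: QC filtering, log-normalization,
silhouette-guided clustering resolution selection, Wilcoxon marker
detection, co-expression AUROC scoring against double-positive cells, and
gene-set module scoring.

Cells live in an :class:`anndata.AnnData` with raw UMI counts in ``.X``
(kept in ``layers['counts']`` after normalization), a boolean ``var['mito']``
flag, and cluster labels in ``obs['cluster']`` once assigned.

The co-expression statistic is the AUROC of a gene's normalized expression
classifying double-positive cells (cells expressing Hand2 together with
Pbx1 and/or Pbx2) versus background mesenchymal cells; it equals the
Mann-Whitney U statistic normalized by the product of the group sizes, so
it is invariant under any strictly monotone transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .intervals import ValidationError

logger = logging.getLogger("limbgrn")

#: resolution grid scanned during clustering selection
DEFAULT_RESOLUTIONS: tuple[float, ...] = tuple(
    round(0.2 + 0.1 * i, 1) for i in range(19)
)  # 0.2 .. 2.0 step 0.1

DEFAULT_AUC_MIN = 0.55


@dataclass(frozen=True)
class QcThresholds:
    """Per-cell quality bounds: total transcripts in [min_total, max_total],
    at least min_genes expressed genes, mitochondrial fraction strictly
    below max_mito_frac."""

    min_total: int = 3000
    max_total: int = 25000
    min_genes: int = 1000
    max_mito_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_total < self.max_total):
            raise ValidationError("require 0 < min_total < max_total")
        if not (0 < self.max_mito_frac < 1):
            raise ValidationError("max_mito_frac must be in (0, 1)")


@dataclass(frozen=True)
class CoexpressionScore:
    gene_id: str
    auc: float
    positive_n: int
    negative_n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"auc must be in [0, 1], got {self.auc}")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def qc_metrics(adata: AnnData) -> pd.DataFrame:
    """Per-cell totals, expressed-gene counts, and mitochondrial fraction
    computed on raw counts."""
    if "mito" not in adata.var:
        raise ValidationError("adata.var['mito'] mitochondrial flags are required")
    X = adata.X
    if sparse.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        mito = np.asarray(X[:, adata.var["mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        totals = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
        mito = X[:, adata.var["mito"].to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {"total_counts": totals, "n_genes": n_genes, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def qc_filter(adata: AnnData, thresholds: QcThresholds = QcThresholds()) -> AnnData:
    """Keep cells with min_total <= total <= max_total, expressed-gene
    count >= min_genes, and mito fraction < max_mito_frac. Genes are left
    unchanged. Idempotent."""
    m = qc_metrics(adata)
    keep = (
        (m["total_counts"] >= thresholds.min_total)
        & (m["total_counts"] <= thresholds.max_total)
        & (m["n_genes"] >= thresholds.min_genes)
        & (m["mito_frac"] < thresholds.max_mito_frac)
    ).to_numpy()
    if keep.sum() == 0:
        logger.warning("qc_filter removed every cell")
    out = adata[keep].copy()
    return out


def log_normalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size log-normalization: value = ln(1 + scale * count /
    cell_total). Raw counts are preserved in ``layers['counts']``;
    all-zero cells stay zero (with a warning)."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero cells left unnormalized", int(zero.sum()))
    denom = np.where(zero, 1.0, totals)
    norm = np.log1p(scale * X / denom[:, None])
    out = adata.copy()
    out.layers["counts"] = X
    out.X = norm
    return out


def highly_variable_subset(adata: AnnData, n_top: int = 5000) -> AnnData:
    """Restrict to the n_top highest-variance genes of the normalized
    matrix (all genes if fewer are present)."""
    X = _dense(adata.X)
    if X.shape[1] <= n_top:
        return adata
    var = X.var(axis=0)
    idx = np.sort(np.argsort(var)[::-1][:n_top])
    return adata[:, idx].copy()


def pca_reduce(adata: AnnData, n_comps: int = 60, seed: int = 0) -> np.ndarray:
    """Principal-component representation of the normalized matrix."""
    X = _dense(adata.X)
    n_comps = min(n_comps, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=seed)
    return pca.fit_transform(X)


# ---------------------------------------------------------------------------
# clustering: pluggable contract (matrix, resolution, seed) -> labels
# ---------------------------------------------------------------------------

Clusterer = Callable[[np.ndarray, float, int], np.ndarray]


def snn_leiden_clusterer(n_neighbors: int = 15) -> Clusterer:
    """Reference clusterer: k-nearest-neighbor graph on the reduced
    representation, Leiden community detection with the given resolution.
    Deterministic for a fixed seed."""
    import igraph
    import leidenalg

    def cluster(X: np.ndarray, resolution: float, seed: int) -> np.ndarray:
        k = min(n_neighbors, X.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        edges = set()
        for i in range(X.shape[0]):
            for j in idx[i, 1:]:
                edges.add((min(i, int(j)), max(i, int(j))))
        g = igraph.Graph(n=X.shape[0], edges=sorted(edges))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)

    return cluster


def select_resolution(
    adata: AnnData,
    clusterer: Optional[Clusterer] = None,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    seed: int = 0,
    n_comps: int = 60,
) -> tuple[float, np.ndarray]:
    """Scan a resolution grid and keep the solution with the highest mean
    silhouette (Euclidean, on the PCA representation), breaking ties toward
    the lowest resolution. Raises if every resolution yields a single
    cluster."""
    if clusterer is None:
        clusterer = snn_leiden_clusterer()
    X = pca_reduce(adata, n_comps=n_comps, seed=seed)
    best: Optional[tuple[float, float, np.ndarray]] = None  # (sil, res, labels)
    for res in resolutions:
        labels = np.asarray(clusterer(X, float(res), seed))
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(X, labels, metric="euclidean"))
        if best is None or sil > best[0]:
            best = (sil, float(res), labels)
    if best is None:
        raise ValidationError("degenerate clustering: single cluster at every resolution")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def find_markers(
    adata: AnnData,
    labels: Sequence,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    fdr_max: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster Wilcoxon rank-sum marker detection on the normalized
    matrix.

    A gene is tested for a cluster iff it is expressed in at least
    ``min_pct`` of the cluster's cells or of the remaining cells, and the
    absolute difference of mean log-expression is >= ``logfc_threshold``.
    Reported p-values are Benjamini-Hochberg corrected within cluster.
    """
    X = _dense(adata.X)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels length must equal number of cells")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least two clusters")
    rows = []
    for lab in uniq:
        mask = labels == lab
        if mask.sum() < 2:
            logger.warning("cluster %r has a single cell; skipped", lab)
            continue
        in_X, out_X = X[mask], X[~mask]
        pct_in = (in_X > 0).mean(axis=0)
        pct_out = (out_X > 0).mean(axis=0)
        diff = in_X.mean(axis=0) - out_X.mean(axis=0)
        tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
            np.abs(diff) >= logfc_threshold
        )
        if not tested.any():
            continue
        res = stats.mannwhitneyu(
            in_X[:, tested], out_X[:, tested], alternative="two-sided", axis=0
        )
        pvals = np.atleast_1d(res.pvalue)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for gi, p, q in zip(np.where(tested)[0], pvals, fdr):
            rows.append(
                {
                    "cluster": lab,
                    "gene_id": adata.var_names[gi],
                    "pct_in": float(pct_in[gi]),
                    "pct_out": float(pct_out[gi]),
                    "log_diff": float(diff[gi]),
                    "p_value": float(p),
                    "fdr": float(q),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["cluster", "gene_id", "pct_in", "pct_out", "log_diff", "p_value", "fdr"],
    )
    return df[df["fdr"] <= fdr_max].reset_index(drop=True)


# ---------------------------------------------------------------------------
# double positives and co-expression AUC
# ---------------------------------------------------------------------------

def double_positive_cells(
    adata: AnnData,
    hand_gene: str = "Hand2",
    pbx_genes: Sequence[str] = ("Pbx1", "Pbx2"),
    floor: float = 0.0,
) -> np.ndarray:
    """Boolean mask of double-positive cells: raw count > floor for the
    HAND gene AND for at least one PBX gene. Uses ``layers['counts']``
    when present, else ``.X``."""
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = _dense(counts)
    names = list(adata.var_names)
    for g in [hand_gene, *pbx_genes]:
        if g not in names:
            raise ValidationError(f"gene {g!r} not in matrix")
    hand = counts[:, names.index(hand_gene)] > floor
    pbx = np.zeros(adata.n_obs, dtype=bool)
    for g in pbx_genes:
        pbx |= counts[:, names.index(g)] > floor
    return hand & pbx


def auc_from_values(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUROC of values separating pos from neg = U / (n1*n2) with midrank
    tie handling."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def coexpression_auc(
    adata: AnnData,
    target: str,
    positive_cells: Sequence,
    background_cells: Sequence,
) -> CoexpressionScore:
    """Co-expression AUROC of a target gene's normalized expression in
    positive (double-positive) versus background cells."""
    names = list(adata.var_names)
    if target not in names:
        raise ValidationError(f"target gene {target!r} not in matrix")
    pos_idx = adata.obs_names.get_indexer(pd.Index(positive_cells))
    neg_idx = adata.obs_names.get_indexer(pd.Index(background_cells))
    if (pos_idx < 0).any() or (neg_idx < 0).any():
        raise ValidationError("unknown cell identifiers in positive/background sets")
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValidationError("positive and background sets must be non-empty")
    if set(pos_idx) & set(neg_idx):
        raise ValidationError("positive and background sets must be disjoint")
    x = _dense(adata.X)[:, names.index(target)]
    auc = auc_from_values(x[pos_idx], x[neg_idx])
    return CoexpressionScore(
        gene_id=target, auc=auc, positive_n=len(pos_idx), negative_n=len(neg_idx)
    )


def coexpression_screen(
    adata: AnnData,
    positive_mask: np.ndarray,
    background_mask: np.ndarray,
    genes: Optional[Sequence[str]] = None,
    auc_min: float = DEFAULT_AUC_MIN,
) -> pd.DataFrame:
    """Vectorized AUROC screen over many genes; returns a table with a
    ``passes`` column at the given threshold (>= 0.55 by default)."""
    positive_mask = np.asarray(positive_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if (positive_mask & background_mask).any():
        raise ValidationError("positive and background masks must be disjoint")
    if positive_mask.sum() == 0 or background_mask.sum() == 0:
        raise ValidationError("positive and background sets must be non-empty")
    X = _dense(adata.X)
    if genes is None:
        cols = np.arange(X.shape[1])
    else:
        names = list(adata.var_names)
        cols = np.array([names.index(g) for g in genes])
    pos = X[positive_mask][:, cols]
    neg = X[background_mask][:, cols]
    n1, n2 = pos.shape[0], neg.shape[0]
    both = np.concatenate([pos, neg], axis=0)
    ranks = stats.rankdata(both, axis=0)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    return pd.DataFrame(
        {
            "gene_id": np.asarray(adata.var_names)[cols],
            "auc": auc,
            "positive_n": n1,
            "negative_n": n2,
            "passes": auc >= auc_min,
        }
    )


# ---------------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------------

def module_score(
    adata: AnnData,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell gene-set score: mean normalized expression of the set minus
    the mean of control genes drawn (seeded) from the same
    average-expression bins.

    For each bin that contains set genes, ``n_ctrl`` control genes per set
    gene are sampled without replacement from the bin (the whole bin if it
    is smaller). Deterministic for a fixed seed.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("gene_set is empty")
    names = list(adata.var_names)
    missing = [g for g in gene_set if g not in names]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing}")
    X = _dense(adata.X)
    avg = X.mean(axis=0)
    order = pd.Series(avg, index=names).rank(method="first")
    n_bins_eff = min(n_bins, len(names))
    bins = pd.qcut(order, n_bins_eff, labels=False)
    rng = np.random.default_rng(seed)
    set_idx = np.array([names.index(g) for g in gene_set])
    ctrl_idx: list[int] = []
    for b in sorted(bins.unique()):
        bin_genes = np.where(bins.to_numpy() == b)[0]
        n_set_in_bin = int(np.isin(set_idx, bin_genes).sum())
        if n_set_in_bin == 0:
            continue
        take = min(n_ctrl * n_set_in_bin, bin_genes.size)
        ctrl_idx.extend(rng.choice(bin_genes, size=take, replace=False).tolist())
    ctrl_idx = sorted(set(ctrl_idx))
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return np.asarray(score, dtype=float)
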