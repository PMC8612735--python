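"""Cluster cells, rank per-cluster marker genes, assign cell types.

Cells are clustered on a kNN graph built in PC space (top 50 components by
default, 0.5% of cells as neighbors with a floor of 15) with Leiden
community detection. Each cluster's top differential genes are then
intersected with a marker-gene database; the significance of each
(cluster, cell type) intersection is an upper-tail hypergeometric p-value,
Bonferroni-corrected over all cluster x type tests, and a cluster is
assigned the type minimizing that corrected p-value (or "unassigned").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom, rankdata

from .errors import ConfigError, ValidationError
from .io_core import CellGeneMatrix, MarkerDB, to_anndata

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ClusterLabels:
    labels: dict[str, int]  # cell_id -> cluster id, contiguous from 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(set(self.labels.values()))
        if ids and ids != list(range(len(ids))):
            raise ValidationError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def as_array(self, cell_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[c] for c in cell_ids])


def log_normalize(m: CellGeneMatrix, target_sum: float = 1e4) -> np.ndarray:
    """ln(1 + count / nUMI * target_sum), dense cells × genes."""
    dense = m.counts.toarray().astype(float)
    n_umi = m.n_umi.astype(float)
    return np.log1p(dense / n_umi[:, None] * target_sum)


def build_clusters(m: CellGeneMatrix, n_pcs: int = 50,
                   neighbor_fraction: float = 0.005,
                   resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """PCA -> kNN graph -> Leiden communities on log-normalized counts.

    k = max(15, round(neighbor_fraction * n_cells)) neighbors per cell on
    Euclidean distance in PC space. Deterministic for a fixed seed.
    """
    import scanpy as sc

    if m.n_cells <= n_pcs:
        raise ConfigError(
            f"{m.n_cells} cells <= {n_pcs} principal components; lower n_pcs"
        )
    adata = to_anndata(m)
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    n_comps = min(n_pcs, m.n_genes - 1)
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    k = max(15, round(neighbor_fraction * m.n_cells))
    k = min(k, m.n_cells - 1)
    sc.pp.neighbors(adata, n_neighbors=k, n_pcs=n_comps, metric="euclidean",
                    random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    raw = adata.obs["leiden"].astype(int).to_numpy()
    # relabel to contiguous ids in first-appearance order for determinism
    remap: dict[int, int] = {}
    labels = {}
    for cell, lab in zip(m.cell_ids, raw):
        labels[cell] = remap.setdefault(int(lab), len(remap))
    return ClusterLabels(labels, params={
        "n_pcs": n_comps, "neighbor_fraction": neighbor_fraction,
        "n_neighbors": k, "resolution": resolution, "seed": seed,
    })


def read_cluster_labels(path) -> ClusterLabels:
    """Alternative entry point: externally computed (cell_id, cluster) TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "cluster"} <= set(df.columns):
        raise ValidationError("labels table needs columns cell_id, cluster")
    return ClusterLabels(dict(zip(df["cell_id"].astype(str),
                                  df["cluster"].astype(int))))


def rank_cluster_markers(m: CellGeneMatrix, labels: ClusterLabels,
                         top_n: int = 100) -> dict[int, list[tuple[str, float]]]:
    """Per-cluster top genes by one-sided rank-sum (overexpression) score.

    For each cluster, every gene gets a tie-corrected Wilcoxon rank-sum z
    score of in-cluster versus all other cells on log-normalized values;
    the cluster's list is the ``top_n`` genes by descending z. Clusters
    with fewer than 3 cells get an empty list (logged).
    """
    if top_n > m.n_genes:
        raise ConfigError(f"top_n={top_n} exceeds {m.n_genes} genes")
    if labels.n_clusters < 2:
        raise ConfigError("need at least 2 clusters to rank markers")
    X = log_normalize(m)
    lab = labels.as_array(m.cell_ids)
    n = m.n_cells
    # per-gene midranks over all cells, with tie correction terms
    ranks = np.apply_along_axis(rankdata, 0, X)
    tie_term = np.zeros(m.n_genes)
    for j in range(m.n_genes):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (cnt ** 3 - cnt).sum()
    out: dict[int, list[tuple[str, float]]] = {}
    for c in range(labels.n_clusters):
        mask = lab == c
        n1 = int(mask.sum())
        if n1 < 3:
            logger.info("cluster %d has %d cells; empty marker list", c, n1)
            out[c] = []
            continue
        n2 = n - n1
        R = ranks[mask].sum(axis=0)
        mu = n1 * (n + 1) / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (R - mu) / np.sqrt(var)
        z = np.where(np.isfinite(z), z, 0.0)
        order = np.lexsort((np.array(m.gene_ids), -z))[:top_n]
        out[c] = [(m.gene_ids[j], float(z[j])) for j in order]
    return out


def hypergeom_overlap_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them markers of a type, ``n``
    drawn as a cluster's top list, ``k`` the observed overlap. The leading
    pmf term at ``k`` is computed exactly (integer combinatorics) and the
    remaining terms follow by the pmf ratio recurrence, so the sum of
    positive decaying ratios stays accurate to ~1e-14 relative; if the
    leading term underflows double precision, a log-space fallback is used.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    lo = max(k, n + K - N)  # support minimum: pmf is exactly 0 below it
    if lo > upper:
        return 0.0
    from fractions import Fraction

    lead = float(Fraction(math.comb(K, lo) * math.comb(N - K, n - lo),
                          math.comb(N, n)))
    if lead == 0.0:  # beyond double-precision range: log-space fallback
        log_terms = hypergeom.logpmf(np.arange(lo, upper + 1), N, K, n)
        return float(min(1.0, math.exp(logsumexp(log_terms))))
    total, term = lead, lead
    for j in range(lo, upper):
        term *= (K - j) * (n - j) / ((j + 1) * (N - K - n + j + 1))
        total += term
    return float(min(1.0, total))


@dataclass
class CellTypeAssignment:
    table: pd.DataFrame  # one row per (cluster, cell_type) test
    assigned: dict[int, str]  # cluster -> type or "unassigned"
    ties: dict[int, list[str]] = field(default_factory=dict)


def assign_cell_types(markers: dict[int, list[tuple[str, float]]] | dict[int, list[str]],
                      db: MarkerDB, genes_tested: list[str],
                      alpha: float = 0.05) -> CellTypeAssignment:
    """Assign each cluster the cell type with the most significant overlap.

    The gene universe is the intersection of the tested matrix's genes with
    the database universe; marker lists and sets are restricted to it. The
    Bonferroni multiplier is n_clusters x n_types (the whole test family).
    Clusters whose best corrected p-value is not below ``alpha`` are left
    "unassigned". Ties on the minimal p-value resolve to the
    lexicographically first type name, with all tied types reported.
    """
    if not db.markers:
        raise ValidationError("empty marker database")
    universe = set(genes_tested) & db.gene_universe
    N = len(universe)
    if N == 0:
        raise ValidationError("no overlap between tested genes and marker universe")
    types = db.cell_types
    n_tests = len(markers) * len(types)
    rows = []
    assigned: dict[int, str] = {}
    ties: dict[int, list[str]] = {}
    for cluster in sorted(markers):
        lst = markers[cluster]
        gene_list = [x[0] if isinstance(x, tuple) else x for x in lst]
        cluster_set = set(gene_list) & universe
        n = len(cluster_set)
        if n == 0:
            logger.info("cluster %d has an empty marker list; unassigned", cluster)
            assigned[cluster] = UNASSIGNED
            for t in types:
                rows.append((cluster, t, 0, 0, len(db.markers[t] & universe), N, 1.0, 1.0))
            continue
        best_p, best_types = math.inf, []
        for t in types:
            marker_set = db.markers[t] & universe
            K = len(marker_set)
            k = len(cluster_set & marker_set)
            raw_p = hypergeom_overlap_p(k, n, K, N) if K else 1.0
            bonf = min(1.0, raw_p * n_tests)
            rows.append((cluster, t, k, n, K, N, raw_p, bonf))
            if bonf < best_p:
                best_p, best_types = bonf, [t]
            elif bonf == best_p:
                best_types.append(t)
        if best_p < alpha:
            assigned[cluster] = sorted(best_types)[0]
            if len(best_types) > 1:
                ties[cluster] = sorted(best_types)
        else:
            assigned[cluster] = UNASSIGNED
    table = pd.DataFrame(rows, columns=[
        "cluster", "cell_type", "overlap_k", "cluster_list_size",
        "marker_set_size", "universe_size", "raw_p", "bonferroni_p",
    ])
    return CellTypeAssignment(table, assigned, ties)


def cell_type_map(labels: ClusterLabels,
                  assignment: CellTypeAssignment) -> dict[str, str]:
    """cell_id -> assigned cell type (or "unassigned")."""
    return {cell: assignment.assigned.get(cl, UNASSIGNED)
            for cell, cl in labels.labels.items()}
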