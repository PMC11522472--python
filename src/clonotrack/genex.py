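"""Single-cell qPCR expression analysis.

Raw Biomark-style data arrive as duplicate Ct readings per (cell, gene).  The
expression value is ``Et = 32 - Ct_min``: the minimum Ct over available
duplicates, with missing readings replaced by the ceiling Ct of 32, so that a
non-detected gene has Et = 0 and Et lives on a log2-like scale in [0, 32].

Cluster marker genes are found with a two-part hurdle test contrasting one
cluster against all other cells:

* a *discrete* component — likelihood-ratio test (1 df) on the detection
  fraction (Et > 0) between groups, a two-binomial logistic contrast;
* a *continuous* component — likelihood-ratio test (1 df) on mean Et among
  expressing cells under a common-variance Gaussian model;
* an *overall* p-value from the summed deviances (2 df, or 1 df when the
  continuous part is undefined).

Markers are the genes passing Bonferroni-corrected overall p <= alpha with
|avg_logFC| > 0.25, where avg_logFC is the in-minus-out difference of mean Et
(base-2 via Ct semantics).  Cohort composition per cluster is compared with a
two-sided rank-sum test on per-donor cell fractions, Bonferroni-corrected over
clusters.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

ET_CEILING = 32.0
CT_MAX = 40.0
HOUSEKEEPING_GENE = "SRP14"


@dataclass
class CtMatrix:
    """Long-form duplicate Ct readings plus per-cell metadata.

    ``ct`` columns: cell_id, gene, replicate (1|2), ct (NaN = missing).
    ``cell_meta`` is indexed by cell_id with donor_id / cohort / phenotype.
    """

    ct: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self):
        missing = {"cell_id", "gene", "replicate", "ct"} - set(self.ct.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        dup = self.ct.groupby(["cell_id", "gene"]).size()
        if (dup > 2).any():
            raise ValueError("more than two duplicate readings for a (cell, gene)")
        if (self.ct["ct"].dropna() <= 0).any():
            raise ValueError("Ct values must be positive")


@dataclass
class ExpressionMatrix:
    """Cells x genes Et values with cell metadata and optional cluster labels."""

    et: pd.DataFrame                       # index: cell_id, columns: genes
    cell_meta: pd.DataFrame                # index: cell_id
    clusters: Optional[pd.Series] = None   # index: cell_id, int labels

    def with_clusters(self, labels: pd.Series) -> "ExpressionMatrix":
        return ExpressionMatrix(self.et, self.cell_meta, labels.reindex(self.et.index))


def read_ct_matrix(ct_path, meta_path) -> CtMatrix:
    ct = pd.read_csv(ct_path, sep="\t", dtype={"cell_id": str, "gene": str})
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
    return CtMatrix(ct=ct, cell_meta=meta)


def preprocess_ct(raw: CtMatrix, ceiling: float = ET_CEILING) -> ExpressionMatrix:
    """Ct duplicates -> Et matrix: Et = ceiling - min(Ct_min, ceiling).

    Readings above 40 cycles are treated as missing (with a warning); a
    (cell, gene) with no usable reading gets Ct = ceiling, hence Et = 0.
    Cells whose entire Et row is zero are removed and logged.
    """
    ct = raw.ct.copy()
    too_high = ct["ct"] > CT_MAX
    if too_high.any():
        logger.warning("%d Ct readings above %.0f treated as missing", int(too_high.sum()), CT_MAX)
        ct.loc[too_high, "ct"] = np.nan
    ct_min = ct.groupby(["cell_id", "gene"])["ct"].min().unstack("gene")
    ct_min = ct_min.reindex(raw.cell_meta.index)
    et = (ceiling - ct_min.clip(upper=ceiling)).fillna(0.0)
    all_zero = (et <= 0).all(axis=1)
    if all_zero.any():
        logger.info("removed %d cells with zero expression in all genes", int(all_zero.sum()))
    et = et.loc[~all_zero]
    meta = raw.cell_meta.loc[et.index]
    return ExpressionMatrix(et=et, cell_meta=meta)


def batch_correct_housekeeping(expr: ExpressionMatrix, batch_col: str = "batch",
                               gene: str = HOUSEKEEPING_GENE) -> ExpressionMatrix:
    """Optional per-run centering of the housekeeping gene's Et.

    Each batch's Et values are shifted so the batch mean of the housekeeping
    gene matches the global mean; off by default in the pipeline.
    """
    if batch_col not in expr.cell_meta.columns:
        raise ValueError(f"no {batch_col!r} column in cell metadata")
    if gene not in expr.et.columns:
        raise ValueError(f"housekeeping gene {gene!r} not measured")
    global_mean = expr.et[gene].mean()
    et = expr.et.copy()
    for batch, idx in expr.cell_meta.groupby(batch_col).groups.items():
        shift = global_mean - expr.et.loc[idx, gene].mean()
        et.loc[idx] = (et.loc[idx] + shift).clip(lower=0.0, upper=ET_CEILING)
    return ExpressionMatrix(et=et, cell_meta=expr.cell_meta, clusters=expr.clusters)


# ---------------------------------------------------------------------------
# Hurdle test
# ---------------------------------------------------------------------------

@dataclass
class HurdleResult:
    gene: str
    cluster: int
    p_continuous: float
    p_discrete: float
    p_overall: float
    avg_logFC: float
    p_adj: Optional[float] = None
    is_marker: Optional[bool] = None


def _binomial_deviance(k1: int, n1: int, k2: int, n2: int) -> float:
    """2*(ll_separate - ll_pooled) for two binomial detection rates."""

    def ll(k, n):
        if n == 0 or k == 0 or k == n:
            # saturated terms with p-hat at 0 or 1 contribute 0
            p = k / n if n else 0.0
            out = 0.0
            if 0 < p < 1:
                out = k * np.log(p) + (n - k) * np.log(1 - p)
            return out
        p = k / n
        return k * np.log(p) + (n - k) * np.log(1 - p)

    pooled_k, pooled_n = k1 + k2, n1 + n2
    return 2.0 * (ll(k1, n1) + ll(k2, n2) - ll(pooled_k, pooled_n))


def _gaussian_deviance(x1: np.ndarray, x2: np.ndarray) -> float:
    """2*(ll_two_means - ll_one_mean) under a common-variance Gaussian MLE.

    Equals n * log(RSS0 / RSS1) with MLE variance profiled out.
    """
    x = np.concatenate([x1, x2])
    n = x.size
    rss0 = float(np.sum((x - x.mean()) ** 2))
    rss1 = float(np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2))
    if rss1 == 0.0:
        return np.inf if rss0 > 0 else 0.0
    return n * np.log(rss0 / rss1)


def hurdle_test(expr: ExpressionMatrix, cluster: int, gene: str) -> HurdleResult:
    """Two-part hurdle test of one gene, cluster-vs-all-other-cells."""
    if expr.clusters is None:
        raise ValueError("ExpressionMatrix has no cluster labels")
    x = expr.et[gene].to_numpy(dtype=float)
    in_mask = (expr.clusters.to_numpy() == cluster)
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need at least 3 cells inside and outside the cluster")
    xi, xo = x[in_mask], x[~in_mask]

    di, do = xi > 0, xo > 0
    dev_disc = _binomial_deviance(int(di.sum()), di.size, int(do.sum()), do.size)
    p_disc = float(stats.chi2.sf(dev_disc, df=1))

    ei, eo = xi[di], xo[do]
    if ei.size >= 1 and eo.size >= 1:
        dev_cont = _gaussian_deviance(ei, eo)
        p_cont = float(stats.chi2.sf(dev_cont, df=1))
        df_total = 2
    else:
        dev_cont, p_cont, df_total = 0.0, 1.0, 1

    p_overall = float(stats.chi2.sf(dev_disc + dev_cont, df=df_total))
    avg_logfc = float(xi.mean() - xo.mean())
    return HurdleResult(gene=gene, cluster=cluster, p_continuous=p_cont,
                        p_discrete=p_disc, p_overall=p_overall, avg_logFC=avg_logfc)


def hurdle_test_all(expr: ExpressionMatrix, alpha: float = 0.05,
                    logfc_threshold: float = 0.25) -> list[HurdleResult]:
    """Run the hurdle test for every (gene, cluster) pair and set markers."""
    clusters = sorted(expr.clusters.dropna().unique())
    results = [hurdle_test(expr, int(cl), g) for cl in clusters for g in expr.et.columns]
    marker_filter(results, alpha=alpha, logfc_threshold=logfc_threshold)
    return results


def marker_filter(results: Sequence[HurdleResult], alpha: float = 0.05,
                  logfc_threshold: float = 0.25,
                  n_tests: Optional[int] = None) -> list[HurdleResult]:
    """Bonferroni-correct overall p-values and keep the marker genes.

    A record is a marker iff ``p_adj <= alpha`` and ``|avg_logFC| > 0.25``
    (threshold configurable).  Mutates p_adj / is_marker in place and returns
    the retained records.
    """
    n = n_tests if n_tests is not None else len(results)
    for r in results:
        r.p_adj = min(1.0, r.p_overall * n)
        r.is_marker = (r.p_adj <= alpha) and (abs(r.avg_logFC) > logfc_threshold)
    return [r for r in results if r.is_marker]


# ---------------------------------------------------------------------------
# Cohort composition
# ---------------------------------------------------------------------------

@dataclass
class ClusterCompositionResult:
    cluster: int
    fractions: pd.Series          # per-donor fraction of that donor's cells here
    p_wilcoxon: float
    p_adj: Optional[float] = None


def donor_cluster_fractions(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-donor fraction of cells in each cluster (rows sum to 1)."""
    df = pd.DataFrame({
        "donor": expr.cell_meta["donor_id"].to_numpy(),
        "cluster": expr.clusters.to_numpy(),
    })
    counts = df.groupby(["donor", "cluster"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def cluster_composition_test(expr: ExpressionMatrix) -> list[ClusterCompositionResult]:
    """Per cluster: two-sided rank-sum test of HD vs T1D per-donor fractions."""
    fracs = donor_cluster_fractions(expr)
    cohort = expr.cell_meta.groupby("donor_id")["cohort"].first().reindex(fracs.index)
    hd = cohort == "HD"
    if hd.sum() < 2 or (~hd).sum() < 2:
        raise ValueError("need at least 2 donors per cohort")
    out = []
    for cl in fracs.columns:
        a = fracs.loc[hd, cl].to_numpy()
        b = fracs.loc[~hd, cl].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out.append(ClusterCompositionResult(cluster=int(cl), fractions=fracs[cl], p_wilcoxon=p))
    n = len(out)
    for r in out:
        r.p_adj = min(1.0, r.p_wilcoxon * n)
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _snn_graph(pcs: np.ndarray, k: int, min_jaccard: float) -> ig.Graph:
    n = pcs.shape[0]
    k = min(k, n)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    idx = nn.kneighbors(return_distance=False)
    # neighbour indicator including self
    rows = np.repeat(np.arange(n), k - 0)
    adj = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, idx.ravel())), shape=(n, n)
    )
    adj = adj.maximum(sparse.eye(n, format="csr", dtype=np.int32))
    shared = (adj @ adj.T).tocoo()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (sizes[r] + sizes[c] - s)
    keep = jac >= min_jaccard
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_cells(expr: ExpressionMatrix, n_pcs: int = 10, resolution: float = 1.0,
                  seed: int = 0, n_neighbors: int = 20,
                  min_jaccard: float = 1.0 / 15.0) -> pd.Series:
    """Scale -> PCA -> shared-nearest-neighbour graph -> Louvain communities.

    Labels are 1-based integers ordered by decreasing cluster size.  The
    Louvain pass is seeded; neighbour count and Jaccard pruning follow common
    SNN defaults (k = 20, prune at 1/15).
    """
    n_cells = expr.et.shape[0]
    if n_cells <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} cells, got {n_cells}")
    if n_cells < n_neighbors:
        raise ValueError(f"fewer cells ({n_cells}) than n_neighbors={n_neighbors}")
    x = expr.et.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    n_comp = min(n_pcs, min(z.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(z)
    g = _snn_graph(pcs, k=n_neighbors, min_jaccard=min_jaccard)
    rng_state = random.getstate()
    try:
        random.seed(seed)
        comm = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        random.setstate(rng_state)
    membership = np.asarray(comm.membership)
    # order 1-based by decreasing size, ties broken by first cell index
    order = sorted(
        np.unique(membership),
        key=lambda m: (-(membership == m).sum(), int(np.argmax(membership == m))),
    )
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([relabel[m] for m in membership], dtype=int)
    return pd.Series(labels, index=expr.et.index, name="cluster")
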