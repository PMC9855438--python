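"""One-vs-rest marker genes with retention rules, and contrast gene sets.

A gene is *retained* as a marker of a cluster when, comparing that cluster's
cells against all other cells on the log-normalized matrix, (i) at least 25%
of in-cluster cells express it, (ii) its log2 fold change is at least 0.25
and (iii) its Benjamini-Hochberg adjusted two-sided Wilcoxon rank-sum p is
below 0.05.  A retained marker additionally enters the *heatmap subset*
when the expressing-cell fraction differs by at least 25 percentage points
inside versus outside the cluster.

The exhaustion-style contrast set uses a linear-scale fold change strictly
greater than 1.5 together with an expressing-fraction difference of at
least 0.25 between the two cell populations.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .scoring import GeneSet

FRAC_IN_MIN = 0.25
LOG2FC_MIN = 0.25
PADJ_MAX = 0.05
HEATMAP_FRAC_DIFF = 0.25
FC_EPS = 1e-9


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def _rank_sum_p(in_mat: np.ndarray, out_mat: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (columns), normal approximation."""
    res = stats.mannwhitneyu(in_mat, out_mat, axis=0, alternative="two-sided", method="asymptotic")
    return np.asarray(res.pvalue)


def find_markers(
    adata: ad.AnnData,
    cluster_col: str = "cluster",
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker table over every cluster with flags per retention rule.

    ``adata.X`` must hold log-normalized expression.  Clusters with fewer
    than ``min_cells`` cells are skipped with a warning recorded in the
    table attribute ``skipped_clusters``.
    """
    if cluster_col not in adata.obs:
        raise KeyError(f"annotation lacks column {cluster_col!r}")
    labels = adata.obs[cluster_col].astype(str).to_numpy()
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for one-vs-rest comparison")
    X = _dense(adata.X)
    genes = np.asarray(adata.var_names)

    rows = []
    skipped = []
    for c in clusters:
        mask = labels == c
        if mask.sum() < min_cells:
            skipped.append(c)
            warnings.warn(f"cluster {c!r} has <{min_cells} cells; skipped", stacklevel=2)
            continue
        in_mat, out_mat = X[mask], X[~mask]
        frac_in = (in_mat > 0).mean(axis=0)
        frac_out = (out_mat > 0).mean(axis=0)
        mean_in = in_mat.mean(axis=0)
        mean_out = out_mat.mean(axis=0)
        log2fc = np.log2((mean_in + FC_EPS) / (mean_out + FC_EPS))
        p = _rank_sum_p(in_mat, out_mat)
        p_adj = multipletests(p, method="fdr_bh")[1]
        retained = (frac_in >= FRAC_IN_MIN) & (log2fc >= LOG2FC_MIN) & (p_adj < PADJ_MAX)
        heatmap = retained & ((frac_in - frac_out) >= HEATMAP_FRAC_DIFF)
        rows.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": genes,
                    "log2FC": log2fc,
                    "frac_in": frac_in,
                    "frac_out": frac_out,
                    "p": p,
                    "p_adj": p_adj,
                    "retained": retained,
                    "heatmap_subset": heatmap,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=[
            "cluster", "gene", "log2FC", "frac_in", "frac_out",
            "p", "p_adj", "retained", "heatmap_subset",
        ]
    )
    table.attrs["skipped_clusters"] = skipped
    return table


def top_markers(table: pd.DataFrame, cluster: str, n: int = 30) -> list[str]:
    """Top retained markers of a cluster, ordered by ascending adjusted p then
    descending log2 fold change — the reference-list rule for bulk signatures."""
    sub = table[(table.cluster == cluster) & table.retained]
    sub = sub.sort_values(["p_adj", "log2FC"], ascending=[True, False])
    return sub.gene.head(n).tolist()


def exhaustion_gene_set(
    adata: ad.AnnData,
    annotation_col: str,
    exhausted: set[str] | list[str],
    non_exhausted: set[str] | list[str],
    name: str = "exhaustion",
    fc_min: float = 1.5,
    frac_diff_min: float = 0.25,
) -> GeneSet:
    """Genes up in exhausted vs non-exhausted cells by linear fold change.

    Kept genes have linear-scale fold change strictly greater than ``fc_min``
    (means on the expm1 scale of the log-normalized matrix) and an
    expressing-fraction difference of at least ``frac_diff_min``.  Intended
    to be called once per lineage (e.g. CD4 and CD8 separately).
    """
    labels = adata.obs[annotation_col].astype(str)
    m_ex = labels.isin(set(exhausted)).to_numpy()
    m_non = labels.isin(set(non_exhausted)).to_numpy()
    if m_ex.sum() == 0 or m_non.sum() == 0:
        raise ValueError("both cluster groups must be non-empty")
    X = _dense(adata.X)
    lin = np.expm1(X)
    mean_ex = lin[m_ex].mean(axis=0)
    mean_non = lin[m_non].mean(axis=0)
    fc = (mean_ex + FC_EPS) / (mean_non + FC_EPS)
    frac_diff = (X[m_ex] > 0).mean(axis=0) - (X[m_non] > 0).mean(axis=0)
    keep = (fc > fc_min) & (frac_diff >= frac_diff_min)
    genes = [g for g, k in zip(adata.var_names, keep) if k]
    if not genes:
        warnings.warn(f"contrast gene set {name!r} is empty", stacklevel=2)
    return GeneSet(name=name, genes=genes)


NAIVENESS_GENES = ("TCF7", "CCR7", "SELL", "LEF1")
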