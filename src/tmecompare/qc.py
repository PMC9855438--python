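"""Gene and cell quality-control filters and the PC feature matrix.

Cells are retained only when they satisfy all four criteria simultaneously:
500-10,000 detected genes (inclusive), 1,000-20,000 UMIs (inclusive),
mitochondrial UMI fraction strictly below 20% and hemoglobin UMI fraction
strictly below 1%.  Genes expressed in fewer than ``min_cells_per_gene``
cells are removed first.  After filtering, counts are library-size
normalized to 10,000 per cell, log1p-transformed, standardized per gene and
projected onto the top principal components (default 100, capped at matrix
rank), which serve as the feature space for the heterogeneity statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from sklearn.decomposition import PCA

# Genes whose names begin with "HB" but are not hemoglobin chains.
HB_FALSE_HITS = frozenset({"HBEGF", "HBS1L", "HBP1"})


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    """Filtering thresholds; range ends inclusive, fraction cutoffs strict."""

    min_cells_per_gene: int = 10
    genes_per_cell_range: tuple[int, int] = (500, 10_000)
    umi_per_cell_range: tuple[int, int] = (1_000, 20_000)
    max_mito_fraction: float = 0.20
    max_hemo_fraction: float = 0.01
    n_components: int = 100
    target_sum: float = 10_000.0

    def validate(self) -> None:
        for lo, hi in (self.genes_per_cell_range, self.umi_per_cell_range):
            if lo > hi:
                raise QCError("range ends must be ordered")
        for f in (self.max_mito_fraction, self.max_hemo_fraction):
            if not 0.0 <= f <= 1.0:
                raise QCError("fraction cutoffs must lie in [0, 1]")


def is_mito(gene_names) -> np.ndarray:
    return np.asarray([g.upper().startswith("MT-") for g in gene_names])


def is_hemo(gene_names) -> np.ndarray:
    return np.asarray(
        [g.upper().startswith("HB") and g.upper() not in HB_FALSE_HITS for g in gene_names]
    )


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Drop genes with nonzero counts in fewer than ``min_cells_per_gene`` cells."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise QCError("empty count matrix")
    X = sparse.csr_matrix(adata.X)
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = cells_per_gene >= thresholds.min_cells_per_gene
    return adata[:, keep].copy()


def _cell_metrics(adata: ad.AnnData) -> pd.DataFrame:
    X = sparse.csr_matrix(adata.X)
    umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = np.asarray(X[:, is_mito(adata.var_names)].sum(axis=1)).ravel()
    hemo = np.asarray(X[:, is_hemo(adata.var_names)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
        hemo_frac = np.where(umi > 0, hemo / np.maximum(umi, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "umi": umi, "mito_frac": mito_frac, "hemo_frac": hemo_frac},
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, dict]:
    """Keep cells passing all four criteria; report per-criterion exclusions.

    The report counts, for each criterion, how many input cells violate it
    (a cell can violate several), alongside input/output totals.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    m = _cell_metrics(adata)
    g_lo, g_hi = thresholds.genes_per_cell_range
    u_lo, u_hi = thresholds.umi_per_cell_range
    ok_genes = (m.n_genes >= g_lo) & (m.n_genes <= g_hi)
    ok_umi = (m.umi >= u_lo) & (m.umi <= u_hi)
    ok_mito = m.mito_frac < thresholds.max_mito_fraction
    ok_hemo = m.hemo_frac < thresholds.max_hemo_fraction
    keep = ok_genes & ok_umi & ok_mito & ok_hemo
    report = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "excluded_by": {
            "genes_per_cell": int((~ok_genes).sum()),
            "umi_per_cell": int((~ok_umi).sum()),
            "mito_fraction": int((~ok_mito).sum()),
            "hemo_fraction": int((~ok_hemo).sum()),
        },
    }
    if keep.sum() == 0:
        raise QCError("no cells survive QC (empty after QC)")
    out = adata[keep.to_numpy()].copy()
    out.obs[m.columns] = m.loc[keep]
    return out, report


def normalize(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Library-size normalization to ``target_sum`` counts per cell, then log1p."""
    out = adata.copy()
    out.X = sparse.csr_matrix(out.X).astype(np.float64)
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def normalize_and_embed(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Normalize, log1p, scale and project onto the top principal components.

    Returns the cells x components score frame (columns ``PC1``..) and the
    per-component variance-explained ratios, ordered decreasing.  Requests
    for more components than the matrix rank are capped with a warning.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    norm = normalize(adata, target_sum=thresholds.target_sum)
    dense = np.asarray(sparse.csr_matrix(norm.X).todense())
    # Per-gene standardization; constant genes contribute nothing.
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (dense - mu) / sd
    max_rank = min(adata.n_obs - 1 if adata.n_obs > 1 else 1, adata.n_vars)
    n_comp = thresholds.n_components
    if n_comp > max_rank:
        warnings.warn(
            f"n_components={n_comp} exceeds matrix rank bound {max_rank}; capping",
            stacklevel=2,
        )
        n_comp = max_rank
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(scaled)
    # Drop numerically null trailing components (rank-deficient input).
    nonnull = pca.explained_variance_ > 1e-12
    if not nonnull.all():
        scores = scores[:, nonnull]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    features = pd.DataFrame(scores, index=adata.obs_names, columns=cols)
    return features, pca.explained_variance_ratio_[nonnull]


def load_embedding(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Load a precomputed embedding (cells x components CSV) as the feature matrix."""
    return pd.read_csv(path, index_col=index_col)
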