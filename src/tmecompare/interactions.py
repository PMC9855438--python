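"""Ligand-receptor interaction significance via a cluster-label permutation null.

For every ligand-receptor pair and every ordered cluster pair (A, B) the
observed statistic is the mean of the ligand's average expression in A and
the receptor's average expression in B; multi-subunit complexes use the
minimum subunit average (the convention of CellPhoneDB-style tools).  A
null distribution is built by shuffling cluster labels across cells, and
the empirical p-value is (1 + #{null >= observed}) / (1 + n_perm), so it is
never exactly zero.  A pair additionally passes an expression-fraction
gate: both the ligand in A and the receptor in B must be expressed in at
least ``min_expr_fraction`` of the cluster's cells, otherwise the entry is
non-significant regardless of p.  Interactions are computed within one
group of cells at a time (e.g. PT-only, then BM-only) so significant-pair
counts can be contrasted between groups.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


def read_pairs(path) -> pd.DataFrame:
    """Two-plus-column TSV: pair id optional, ligand, receptor; subunits comma-separated."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    lig, rec = cols.get("ligand"), cols.get("receptor")
    if lig is None or rec is None:
        raise ValueError("pair table needs 'ligand' and 'receptor' columns")
    out = df.rename(columns={lig: "ligand", rec: "receptor"})
    if "pair_id" not in out.columns:
        out["pair_id"] = out.ligand + "_" + out.receptor
    return out[["pair_id", "ligand", "receptor"]]


def _subunits(field: str) -> list[str]:
    return [g.strip() for g in str(field).split(",") if g.strip()]


def lr_significance(
    adata: ad.AnnData,
    pairs: pd.DataFrame,
    cluster_col: str = "cluster",
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_expr_fraction: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation significance of each LR pair for every ordered cluster pair.

    ``adata.X`` holds log-normalized expression; ``pairs`` has columns
    ``pair_id``, ``ligand``, ``receptor``.  Returns a long table with
    columns ``pair_id, ligand_cluster, receptor_cluster, mean_score, p,
    gate, significant``.  Pairs whose genes are absent are dropped with a
    warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    universe = set(adata.var_names)
    resolved = []
    for row in pairs.itertuples(index=False):
        lg, rg = _subunits(row.ligand), _subunits(row.receptor)
        if all(g in universe for g in lg + rg):
            resolved.append((row.pair_id, lg, rg))
        else:
            warnings.warn(f"pair {row.pair_id!r} has unresolvable genes; dropped", stacklevel=2)
    if not resolved:
        raise ValueError("no resolvable ligand-receptor pairs")

    genes = sorted({g for _, lg, rg in resolved for g in lg + rg})
    gi = {g: k for k, g in enumerate(genes)}
    X = adata[:, genes].X
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)

    labels = adata.obs[cluster_col].astype(str).to_numpy()
    clusters = sorted(pd.unique(labels))
    small = [c for c in clusters if (labels == c).sum() < 5]
    if small:
        warnings.warn(f"clusters with <5 cells: {small}", stacklevel=2)
    onehot = np.stack([(labels == c).astype(float) for c in clusters])
    sizes = onehot.sum(axis=1, keepdims=True)

    def cluster_means(mat_onehot):
        return (mat_onehot @ X) / sizes

    def pair_stats(means):
        # stat[p, A, B] = (min-subunit ligand mean in A + receptor mean in B)/2
        out = np.empty((len(resolved), len(clusters), len(clusters)))
        for p, (_, lg, rg) in enumerate(resolved):
            lmean = means[:, [gi[g] for g in lg]].min(axis=1)
            rmean = means[:, [gi[g] for g in rg]].min(axis=1)
            out[p] = (lmean[:, None] + rmean[None, :]) / 2.0
        return out

    obs_means = cluster_means(onehot)
    frac = (onehot @ (X > 0)) / sizes
    observed = pair_stats(obs_means)

    exceed = np.zeros_like(observed)
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        perm_onehot = np.stack([(perm_labels == c).astype(float) for c in clusters])
        null = pair_stats((perm_onehot @ X) / perm_onehot.sum(axis=1, keepdims=True))
        exceed += null >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for p, (pair_id, lg, rg) in enumerate(resolved):
        lfrac = frac[:, [gi[g] for g in lg]].min(axis=1)
        rfrac = frac[:, [gi[g] for g in rg]].min(axis=1)
        for a, ca in enumerate(clusters):
            for b, cb in enumerate(clusters):
                gate = bool(lfrac[a] >= min_expr_fraction and rfrac[b] >= min_expr_fraction)
                pv = float(pvals[p, a, b])
                rows.append(
                    {
                        "pair_id": pair_id,
                        "ligand_cluster": ca,
                        "receptor_cluster": cb,
                        "mean_score": float(observed[p, a, b]),
                        "p": pv,
                        "gate": gate,
                        "significant": bool(gate and pv < alpha),
                    }
                )
    result = pd.DataFrame(rows)
    result.attrs["alpha"] = alpha
    result.attrs["n_perm"] = n_perm
    return result


def count_significant(result: pd.DataFrame) -> pd.DataFrame:
    """Cluster x cluster matrix counting significant pairs (rows: ligand cluster)."""
    clusters = sorted(set(result.ligand_cluster) | set(result.receptor_cluster))
    mat = pd.DataFrame(0, index=clusters, columns=clusters)
    sig = result[result.significant]
    for (a, b), sub in sig.groupby(["ligand_cluster", "receptor_cluster"], observed=True):
        mat.loc[a, b] = len(sub)
    return mat


def lr_by_group(
    adata: ad.AnnData,
    pairs: pd.DataFrame,
    group_col: str = "group",
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run :func:`lr_significance` separately within each cell group."""
    out = {}
    for g in sorted(pd.unique(adata.obs[group_col].astype(str))):
        sub = adata[(adata.obs[group_col].astype(str) == g).to_numpy()]
        out[g] = lr_significance(sub, pairs, **kwargs)
    return out
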