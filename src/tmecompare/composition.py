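"""Per-sample cell-type composition, clustering and proportion correlations.

Composition is reported both as proportions (each sample's rows sum to 1)
and as rates per 10,000 cells, the convention used when contrasting
infiltration between groups (e.g. T/NK cells at 2,051 vs 1,548 per 10,000
in primary tumors vs brain metastases).  Samples can be hierarchically
clustered on their proportion vectors (Ward linkage) and cut into two
groups whose agreement with the PT/BM labels is scored by best-matching
accuracy; pairwise cell-type proportion correlations use Pearson or
Spearman with their standard nulls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


def composition(
    annotation: pd.DataFrame,
    type_col: str = "cluster",
    sample_col: str = "sample",
    group_col: str = "group",
) -> dict[str, pd.DataFrame]:
    """Per-sample counts, proportions and per-10,000 rates for each cell type.

    Zero-count types appear as explicit zeros.  Returns a dict with keys
    ``counts``, ``proportions``, ``per_10k`` (samples x types frames) and
    ``groups`` (sample -> group series).
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    counts = (
        annotation.groupby([sample_col, type_col], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=1)
    )
    proportions = counts.div(counts.sum(axis=1), axis=0)
    groups = annotation.groupby(sample_col, observed=True)[group_col].first()
    return {
        "counts": counts,
        "proportions": proportions,
        "per_10k": proportions * 10_000,
        "groups": groups.loc[counts.index],
    }


def clr_transform(proportions: pd.DataFrame, pseudo: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform, for users wary of compositional artifacts."""
    logp = np.log(proportions + pseudo)
    return logp.sub(logp.mean(axis=1), axis=0)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_samples_by_composition(
    comp: dict[str, pd.DataFrame], use_clr: bool = False
) -> dict:
    """Ward clustering of samples on composition vectors, cut at two groups.

    Agreement is the best-matching accuracy between the 2-group cut and the
    samples' group labels (max over the two label assignments, so chance is
    about 0.5).  Identical compositions across all samples are flagged
    non-informative.
    """
    proportions = comp["proportions"]
    groups = comp["groups"]
    if proportions.shape[0] < 4:
        raise ValueError("need at least four samples to cluster")
    mat = clr_transform(proportions) if use_clr else proportions
    Z = hierarchy.linkage(mat.to_numpy(), method="ward")
    assign = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = groups.astype(str).to_numpy()
    uniq = np.unique(labels)
    if len(uniq) == 2:
        acc1 = np.mean((assign == 1) == (labels == uniq[0]))
        agreement = float(max(acc1, 1 - acc1))
    else:
        agreement = float("nan")
    non_informative = bool(np.allclose(mat.to_numpy(), mat.to_numpy()[0], atol=1e-12))
    return {
        "linkage": Z,
        "assignment": pd.Series(assign, index=proportions.index, name="cluster2"),
        "agreement": agreement,
        "non_informative": non_informative,
        "newick": _linkage_to_newick(Z, proportions.index.tolist()),
    }


def proportion_correlations(
    comp: dict[str, pd.DataFrame], method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type x type correlation matrix of per-sample proportions with p-values.

    Constant columns have undefined correlations, reported as NaN.
    """
    proportions = comp["proportions"]
    if proportions.shape[0] < 3:
        raise ValueError("need at least three samples")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    types = proportions.columns
    R = pd.DataFrame(np.eye(len(types)), index=types, columns=types)
    P = pd.DataFrame(np.zeros((len(types), len(types))), index=types, columns=types)
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            if j <= i:
                continue
            x, y = proportions[a].to_numpy(), proportions[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                res = fn(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            R.loc[a, b] = R.loc[b, a] = r
            P.loc[a, b] = P.loc[b, a] = p
    np.fill_diagonal(P.values, 0.0)
    return R, P


def compare_group_proportions(
    comp: dict[str, pd.DataFrame], group_col_values: tuple[str, str] = ("PT", "BM")
) -> pd.DataFrame:
    """Per-type Wilcoxon rank-sum of sample proportions between the two groups."""
    proportions = comp["proportions"]
    groups = comp["groups"].astype(str)
    a_mask = (groups == group_col_values[0]).to_numpy()
    b_mask = (groups == group_col_values[1]).to_numpy()
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise ValueError("both groups must be present")
    rows = []
    for t in proportions.columns:
        x = proportions.loc[a_mask, t]
        y = proportions.loc[b_mask, t]
        stat, p = stats.ranksums(x, y)
        rows.append(
            {
                "cell_type": t,
                f"mean_per10k_{group_col_values[0]}": float(x.mean() * 10_000),
                f"mean_per10k_{group_col_values[1]}": float(y.mean() * 10_000),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out.p, method="fdr_bh")[1]
    return out
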