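"""Per-tumor heterogeneity in PC feature space.

The heterogeneity score of a sample with ``m`` cells and ``n`` features is
the average Euclidean distance of its cells from a centroid,

    score = (1/m) * sum_i sqrt( sum_j (x_ij - y_j)^2 ),

where ``x_ij`` is cell *i*'s *j*-th feature.  For the *intra*-tumoral
variant the centroid ``y`` is that sample's own cell centroid (optionally
the full-dataset centroid via ``intra_centroid='dataset'``); for the
*inter*-tumoral variant it is the centroid of all cells in the sample's
group (PT or BM).  Raw scores are Z-normalized across samples within each
variant, and groups are compared by a two-sided Wilcoxon rank-sum test on
the per-sample Z scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _mean_distance(points: np.ndarray, centroid: np.ndarray) -> float:
    return float(np.sqrt(((points - centroid) ** 2).sum(axis=1)).mean())


def heterogeneity_score(
    features: pd.DataFrame,
    annotation: pd.DataFrame,
    mode: str = "intra",
    sample_col: str = "sample",
    group_col: str = "group",
    intra_centroid: str = "sample",
) -> pd.DataFrame:
    """Per-sample raw and Z-normalized heterogeneity scores for one mode.

    ``features`` is the cells x components matrix; ``annotation`` assigns
    every cell to exactly one sample and group.  Returns one row per sample
    with columns ``sample, group, m, raw, z``.
    """
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    if intra_centroid not in ("sample", "dataset"):
        raise ValueError("intra_centroid must be 'sample' or 'dataset'")
    annot = annotation.loc[features.index]
    if annot[[sample_col, group_col]].isna().any().any():
        raise ValueError("every cell needs a sample and a group label")
    X = features.to_numpy(dtype=float)
    samples = annot[sample_col].astype(str).to_numpy()
    groups = annot[group_col].astype(str).to_numpy()
    group_of = dict(zip(samples, groups))
    if len(set(groups)) == 0:
        raise ValueError("empty group structure")

    dataset_centroid = X.mean(axis=0)
    group_centroids = {g: X[groups == g].mean(axis=0) for g in np.unique(groups)}

    rows = []
    for s in pd.unique(samples):
        mask = samples == s
        pts = X[mask]
        if mode == "intra":
            centroid = pts.mean(axis=0) if intra_centroid == "sample" else dataset_centroid
        else:
            centroid = group_centroids[group_of[s]]
        if mode == "intra" and pts.shape[0] == 1:
            warnings.warn(f"sample {s!r} has a single cell; intra score is 0", stacklevel=2)
        rows.append(
            {
                "sample": s,
                "group": group_of[s],
                "m": int(mask.sum()),
                "raw": _mean_distance(pts, centroid),
            }
        )
    result = pd.DataFrame(rows)
    sd = result.raw.std(ddof=0)
    result["z"] = 0.0 if sd == 0 else (result.raw - result.raw.mean()) / sd
    result.attrs["mode"] = mode
    return result


def heterogeneity_both(
    features: pd.DataFrame,
    annotation: pd.DataFrame,
    sample_col: str = "sample",
    group_col: str = "group",
    intra_centroid: str = "sample",
) -> pd.DataFrame:
    """Intra and inter variants merged into one per-sample table."""
    intra = heterogeneity_score(
        features, annotation, "intra", sample_col, group_col, intra_centroid
    )
    inter = heterogeneity_score(features, annotation, "inter", sample_col, group_col)
    out = intra.rename(columns={"raw": "intra_raw", "z": "intra_z"}).merge(
        inter.rename(columns={"raw": "inter_raw", "z": "inter_z"})[
            ["sample", "inter_raw", "inter_z"]
        ],
        on="sample",
    )
    return out


def compare_groups(
    result: pd.DataFrame, mode: str = "intra", group_col: str = "group"
) -> dict:
    """Two-sided Wilcoxon rank-sum on per-sample Z scores between the two groups."""
    col = f"{mode}_z" if f"{mode}_z" in result else "z"
    groups = result[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = result.loc[result[group_col] == groups[0], col].to_numpy()
    b = result.loc[result[group_col] == groups[1], col].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    stat, p = stats.ranksums(a, b)
    return {
        "mode": mode,
        "groups": list(map(str, groups)),
        "statistic": float(stat),
        "p": float(p),
        "medians": {str(groups[0]): float(np.median(a)), str(groups[1]): float(np.median(b))},
    }
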