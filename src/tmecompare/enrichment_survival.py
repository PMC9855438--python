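"""ssGSEA bulk validation, median-split survival, and group pathway contrasts.

The single-sample GSEA statistic ranks a sample's genes by decreasing
expression and accumulates the difference between a rank-weighted empirical
CDF over set genes (weights ``rank^alpha``, top gene carrying rank N) and
the unweighted CDF over non-set genes; the enrichment score is the sum of
that difference over all positions.  With ``alpha = 0`` the statistic
reduces to an unweighted CDF difference (a Kolmogorov-Smirnov-like running
sum).  Scores are optionally range-normalized across samples.

Survival validation splits a bulk cohort at the median signature score
(ties to the low group) and compares the two Kaplan-Meier curves with the
log-rank test.  Pathway contrasts score cells per gene set and compare the
two sample groups per set with Wilcoxon rank-sum and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import GeneSet, _expr_frame, auc_recovery_score

DEFAULT_ALPHA = 0.25  # ssGSEA's published rank-weight exponent


def _ssgsea_single(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score of one sample; ``values`` aligned with ``in_set``."""
    order = np.argsort(-values, kind="stable")
    hits = in_set[order]
    n = len(values)
    s = int(hits.sum())
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene weighted N
    w = np.where(hits, ranks**alpha, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~hits) / (n - s)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_score(
    expression,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample ssGSEA enrichment score for one gene set.

    ``expression`` is samples x genes.  Set genes absent from the matrix
    are dropped (error if none remain); expression ties are broken by
    lexicographic gene identifier.  With ``normalize`` and at least two
    samples, scores are divided by their range across samples.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    df = _expr_frame(expression)
    present = [g for g in gene_set.genes if g in df.columns]
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    if len(present) >= df.shape[1]:
        raise ValueError("gene set must be a strict subset of the gene universe")
    df = df[sorted(df.columns)]
    in_set = np.asarray(df.columns.isin(present))
    scores = np.array([_ssgsea_single(row, in_set, alpha) for row in df.to_numpy()])
    if normalize and len(scores) > 1:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
    return pd.Series(scores, index=df.index, name=gene_set.name)


def median_split_logrank(survival: pd.DataFrame, scores: pd.Series) -> dict:
    """Median-split Kaplan-Meier comparison by the log-rank test.

    ``survival`` needs ``time`` (>0, days) and ``event`` (0/1) columns
    indexed like ``scores``.  High group: score strictly above the median;
    ties go low.  Raises on a degenerate (single-group) split.
    """
    common = survival.index.intersection(scores.index)
    if len(common) < 4:
        raise ValueError("need at least four samples with both score and survival")
    surv = survival.loc[common]
    sc = scores.loc[common]
    if surv.event.sum() < 1:
        raise ValueError("need at least one event")
    if sc.nunique() == 1:
        raise ValueError("degenerate split: all scores identical")
    med = sc.median()
    high = sc > med
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("degenerate split: median split produced one group")
    res = logrank_test(
        surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
    )
    return {
        "signature": scores.name,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "median_score": float(med),
        "assignment": pd.Series(np.where(high, "high", "low"), index=common),
    }


def pathway_contrast(
    expression,
    annotation: pd.Series,
    gene_sets: list[GeneSet],
    contrast: tuple[str, str],
    engine: str = "ssgsea",
    **engine_kwargs,
) -> pd.DataFrame:
    """Per-set activity difference between two groups of cells or samples.

    Scores each observation per set (``engine`` 'ssgsea' or 'auc'), then a
    two-sided Wilcoxon rank-sum between the contrast groups with BH
    adjustment across sets.  ``delta`` is the median score difference
    (first contrast group minus second).
    """
    if engine == "ssgsea":
        scorer = lambda s: ssgsea_score(expression, s, **engine_kwargs)  # noqa: E731
    elif engine == "auc":
        scorer = lambda s: auc_recovery_score(expression, s, **engine_kwargs)  # noqa: E731
    else:
        raise ValueError("engine must be 'ssgsea' or 'auc'")
    labels = annotation.astype(str)
    if (labels == contrast[0]).sum() == 0 or (labels == contrast[1]).sum() == 0:
        raise ValueError("both contrast groups must be non-empty")
    rows = []
    for gs in gene_sets:
        try:
            sc = scorer(gs)
        except ValueError:
            continue  # set empty after intersection: dropped
        lab = labels.reindex(sc.index)
        a = sc[(lab == contrast[0]).to_numpy()].to_numpy()
        b = sc[(lab == contrast[1]).to_numpy()].to_numpy()
        stat, p = stats.ranksums(a, b)
        rows.append(
            {
                "gene_set": gs.name,
                "delta": float(np.median(a) - np.median(b)),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = multipletests(out.p, method="fdr_bh")[1]
    return out
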