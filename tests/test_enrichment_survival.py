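"""ssGSEA statistic, median-split log-rank, and pathway contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tmecompare import enrichment_survival as es
from tmecompare import syndata
from tmecompare.scoring import GeneSet


def _bulk(rng, n_samples=6, n_genes=30):
    genes = [f"G{j:02d}" for j in range(n_genes)]
    return pd.DataFrame(
        rng.exponential(1.0, size=(n_samples, n_genes)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=genes,
    )


class TestSsgsea:
    def test_top_placement_is_maximal_over_exhaustive_placements(self):
        """On a 10-gene sample, the set at the top |S| ranks beats every other
        placement of |S| genes."""
        genes = [f"G{j}" for j in range(10)]
        values = np.arange(10, 0, -1, dtype=float)
        df = pd.DataFrame([values], columns=genes)
        scores = {
            sub: es.ssgsea_score(df, GeneSet("s", list(sub)), normalize=False).iloc[0]
            for sub in itertools.combinations(genes, 3)
        }
        top = tuple(genes[:3])
        assert scores[top] == max(scores.values())

    def test_identical_samples_identical_scores(self, rng):
        df = _bulk(rng, n_samples=1)
        df2 = pd.concat([df, df.set_axis(["s1"])])
        s = es.ssgsea_score(df2, GeneSet("s", list(df.columns[:5])), normalize=False)
        assert s.iloc[0] == s.iloc[1]

    def test_alpha_zero_reduces_to_unweighted_cdf_difference(self, rng):
        """Independent running-sum oracle with unit weights."""
        df = _bulk(rng, n_samples=4)
        sub = list(df.columns[::6])
        got = es.ssgsea_score(df, GeneSet("s", sub), alpha=0.0, normalize=False)
        for i in range(4):
            row = df.iloc[i]
            order = sorted(df.columns, key=lambda g: (-row[g], g))
            hits = np.array([g in sub for g in order])
            expected = float(
                np.sum(np.cumsum(hits) / hits.sum() - np.cumsum(~hits) / (~hits).sum())
            )
            assert got.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        df = _bulk(rng)
        gs = GeneSet("s", list(df.columns[:4]))
        s1 = es.ssgsea_score(df, gs, normalize=False)
        s2 = es.ssgsea_score(np.log1p(df) * 7, gs, normalize=False)
        assert np.allclose(s1, s2)

    def test_empty_intersection_errors(self, rng):
        with pytest.raises(ValueError):
            es.ssgsea_score(_bulk(rng), GeneSet("s", ["NOPE"]))


class TestMedianSplit:
    def _surv(self, n, rng, scale=500.0):
        return pd.DataFrame(
            {
                "time": rng.exponential(scale, size=n),
                "event": rng.integers(0, 2, size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_identical_survival_distributions_large_p(self, rng):
        n = 100
        surv = self._surv(n, rng)
        surv.event = 1
        # identical survival in both halves: duplicate times across the split
        surv.iloc[n // 2 :, 0] = surv.iloc[: n // 2, 0].to_numpy()
        scores = pd.Series(np.arange(n, dtype=float), index=surv.index, name="sig")
        out = es.median_split_logrank(surv, scores)
        assert out["p"] > 0.5

    def test_distinct_scores_even_n_equal_groups(self, rng):
        n = 40
        surv = self._surv(n, rng)
        scores = pd.Series(rng.normal(size=n), index=surv.index, name="sig")
        out = es.median_split_logrank(surv, scores)
        assert out["n_high"] == out["n_low"] == n // 2

    def test_identical_scores_degenerate_error(self, rng):
        surv = self._surv(10, rng)
        scores = pd.Series(1.0, index=surv.index, name="sig")
        with pytest.raises(ValueError, match="degenerate"):
            es.median_split_logrank(surv, scores)

    def test_planted_hazard_ratio_detected(self):
        expr, surv, sig = syndata.simulate_bulk_survival(
            n_samples=200, hazard_ratio=3.0, seed=17
        )
        scores = es.ssgsea_score(expr, GeneSet("sig", sig))
        out = es.median_split_logrank(surv, scores)
        assert out["p"] < 0.01


class TestPathwayContrast:
    def _data(self, rng, shift=0.0):
        df = _bulk(rng, n_samples=120, n_genes=40)
        labels = pd.Series(["PT"] * 60 + ["BM"] * 60, index=df.index)
        planted = list(df.columns[:6])
        df.loc[labels == "PT", planted] += shift
        return df, labels, planted

    def test_identical_groups_have_large_adjusted_p(self, rng):
        df, labels, planted = self._data(rng, shift=0.0)
        sets = [GeneSet("planted", planted), GeneSet("null", list(df.columns[10:16]))]
        out = es.pathway_contrast(df, labels, sets, ("PT", "BM"))
        assert (out.p_adj > 0.05).all()

    def test_planted_shift_detected_with_direction(self, rng):
        df, labels, planted = self._data(rng, shift=3.0)
        sets = [GeneSet("planted", planted), GeneSet("null", list(df.columns[10:16]))]
        out = es.pathway_contrast(df, labels, sets, ("PT", "BM")).set_index("gene_set")
        assert out.loc["planted", "p_adj"] < 0.05
        assert out.loc["planted", "delta"] > 0

    def test_label_permutation_destroys_significance(self, rng):
        df, labels, planted = self._data(rng, shift=3.0)
        sets = [GeneSet("planted", planted)]
        perm_rng = np.random.default_rng(23)
        hits = 0
        for _ in range(20):
            perm = pd.Series(
                perm_rng.permutation(labels.to_numpy()), index=labels.index
            )
            out = es.pathway_contrast(df, perm, sets, ("PT", "BM"))
            hits += int(out.p_adj.iloc[0] < 0.05)
        assert hits <= 3
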