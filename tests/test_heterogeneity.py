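"""Heterogeneity statistic: oracles, geometric invariances, group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmecompare import heterogeneity as het
from tmecompare import qc, syndata


def _annot(samples, groups):
    idx = [f"c{i}" for i in range(len(samples))]
    return pd.DataFrame({"sample": samples, "group": groups}, index=idx)


def _features(points):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        pts, index=[f"c{i}" for i in range(len(pts))],
        columns=[f"PC{j + 1}" for j in range(pts.shape[1])],
    )


def test_two_point_sample_gives_unit_score():
    feats = _features([(0, 0), (2, 0)])
    annot = _annot(["A", "A"], ["PT", "PT"])
    res = het.heterogeneity_score(feats, annot, "intra")
    assert res.raw.iloc[0] == pytest.approx(1.0)


def test_identical_cells_score_zero():
    feats = _features([(1.5, -2.0)] * 6)
    res = het.heterogeneity_score(feats, _annot(["A"] * 6, ["PT"] * 6), "intra")
    assert res.raw.iloc[0] == 0.0


def _brute_force(feats, annot, mode, intra_centroid="sample"):
    X = feats.to_numpy()
    out = {}
    for s in annot["sample"].unique():
        mask = (annot["sample"] == s).to_numpy()
        if mode == "intra":
            y = X.mean(axis=0) if intra_centroid == "dataset" else X[mask].mean(axis=0)
        else:
            g = annot.loc[annot["sample"] == s, "group"].iloc[0]
            y = X[(annot["group"] == g).to_numpy()].mean(axis=0)
        total = 0.0
        for i in np.flatnonzero(mask):
            total += np.sqrt(np.sum((X[i] - y) ** 2))
        out[s] = total / mask.sum()
    return out


def test_raw_scores_match_per_cell_distance_loop(gaussian_samples):
    feats, annot, _ = gaussian_samples
    for mode in ("intra", "inter"):
        res = het.heterogeneity_score(feats, annot, mode)
        oracle = _brute_force(feats, annot, mode)
        for _, row in res.iterrows():
            assert row.raw == pytest.approx(oracle[row["sample"]], abs=1e-10)


def test_dataset_centroid_option_matches_its_oracle(gaussian_samples):
    feats, annot, _ = gaussian_samples
    res = het.heterogeneity_score(feats, annot, "intra", intra_centroid="dataset")
    oracle = _brute_force(feats, annot, "intra", intra_centroid="dataset")
    for _, row in res.iterrows():
        assert row.raw == pytest.approx(oracle[row["sample"]], abs=1e-10)


def test_scores_rank_correlate_with_planted_spread(gaussian_samples):
    feats, annot, sds = gaussian_samples
    res = het.heterogeneity_score(feats, annot, "intra")
    rho, _ = stats.spearmanr(res.raw, [sds[s] for s in res["sample"]])
    assert rho >= 0.9


def test_rigid_rotation_and_translation_invariance(gaussian_samples):
    feats, annot, _ = gaussian_samples
    Q = stats.ortho_group.rvs(feats.shape[1], random_state=0)
    moved = pd.DataFrame(feats.to_numpy() @ Q + 5.0, index=feats.index, columns=feats.columns)
    for mode in ("intra", "inter"):
        r1 = het.heterogeneity_score(feats, annot, mode).raw.to_numpy()
        r2 = het.heterogeneity_score(moved, annot, mode).raw.to_numpy()
        assert np.allclose(r1, r2, atol=1e-8)


def test_positive_homogeneity_degree_one(gaussian_samples):
    feats, annot, _ = gaussian_samples
    r1 = het.heterogeneity_score(feats, annot, "intra").raw.to_numpy()
    r2 = het.heterogeneity_score(2.0 * feats, annot, "intra").raw.to_numpy()
    assert np.allclose(r2, 2.0 * r1)


def test_triangle_inequality_bound(gaussian_samples):
    feats, annot, _ = gaussian_samples
    both = het.heterogeneity_both(feats, annot)
    X = feats.to_numpy()
    for _, row in both.iterrows():
        mask = (annot["sample"] == row["sample"]).to_numpy()
        gmask = (annot["group"] == row["group"]).to_numpy()
        d = np.sqrt(np.sum((X[mask].mean(0) - X[gmask].mean(0)) ** 2))
        assert row.intra_raw <= row.inter_raw + d + 1e-12


def test_z_scores_are_standardized(gaussian_samples):
    feats, annot, _ = gaussian_samples
    both = het.heterogeneity_both(feats, annot)
    for col in ("intra_z", "inter_z"):
        assert both[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert both[col].std(ddof=0) == pytest.approx(1.0)


def test_intra_and_inter_strongly_correlated_on_default_syndata():
    cfg = syndata.SimConfig(n_samples_per_group=5, n_cells_per_sample=100,
                            n_genes=300, n_clusters=3, markers_per_cluster=10, seed=8)
    adata, _ = syndata.simulate_counts(cfg)
    feats, _ = qc.normalize_and_embed(adata, qc.QCThresholds(n_components=20))
    both = het.heterogeneity_both(feats, adata.obs)
    rho, _ = stats.spearmanr(both.intra_raw, both.inter_raw)
    assert rho > 0.7


def test_single_cell_sample_warns_and_scores_zero():
    feats = _features([(0, 0), (1, 1), (2, 2)])
    annot = _annot(["A", "A", "B"], ["PT", "PT", "PT"])
    with pytest.warns(UserWarning, match="single cell"):
        res = het.heterogeneity_score(feats, annot, "intra")
    assert res.set_index("sample").loc["B", "raw"] == 0.0


class TestCompareGroups:
    def _result(self, a_scores, b_scores):
        rows = [{"sample": f"A{i}", "group": "PT", "intra_z": v} for i, v in enumerate(a_scores)]
        rows += [{"sample": f"B{i}", "group": "BM", "intra_z": v} for i, v in enumerate(b_scores)]
        return pd.DataFrame(rows)

    def test_identical_distributions_give_large_p(self):
        vals = list(np.linspace(-1, 1, 30))
        out = het.compare_groups(self._result(vals, vals), "intra")
        assert out["p"] > 0.9

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        r = self._result(a, b)
        out1 = het.compare_groups(r, "intra")
        swapped = r.assign(group=r.group.map({"PT": "BM", "BM": "PT"}))
        out2 = het.compare_groups(swapped, "intra")
        assert out1["p"] == pytest.approx(out2["p"])
        assert abs(out1["statistic"]) == pytest.approx(abs(out2["statistic"]))
        # medians travel with the labels
        assert out1["medians"]["PT"] == pytest.approx(out2["medians"]["BM"])

    def test_single_sample_group_errors(self):
        with pytest.raises(ValueError):
            het.compare_groups(self._result([1.0], [0.0, 0.5, 1.0]), "intra")
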