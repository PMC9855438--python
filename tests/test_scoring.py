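"""Signature-score engines and the regulon activation rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmecompare import scoring
from tmecompare.scoring import GeneSet, RegulonActivity


def _frame(rng, n_cells=10, n_genes=20):
    genes = [f"G{j:02d}" for j in range(n_genes)]
    return pd.DataFrame(
        rng.exponential(1.0, size=(n_cells, n_genes)),
        index=[f"c{i}" for i in range(n_cells)],
        columns=genes,
    )


class TestMeanScore:
    def test_matches_hand_computed_row_means(self, rng):
        df = _frame(rng)
        genes = ["G03", "G07", "G11", "G15", "G19"]
        score = scoring.mean_signature_score(df, GeneSet("s", genes))
        expected = df[genes].to_numpy().mean(axis=1)
        assert np.allclose(score.to_numpy(), expected)

    def test_zero_expression_gives_zero_score(self, rng):
        df = _frame(rng)
        df.loc["c0", ["G01", "G02"]] = 0.0
        score = scoring.mean_signature_score(df, GeneSet("s", ["G01", "G02"]))
        assert score["c0"] == 0.0

    def test_single_gene_set_is_identity(self, rng):
        df = _frame(rng)
        score = scoring.mean_signature_score(df, GeneSet("s", ["G05"]))
        assert np.allclose(score.to_numpy(), df["G05"].to_numpy())

    def test_linearity_in_expression(self, rng):
        df = _frame(rng)
        gs = GeneSet("s", ["G00", "G04"])
        assert np.allclose(
            scoring.mean_signature_score(3.5 * df, gs),
            3.5 * scoring.mean_signature_score(df, gs),
        )

    def test_missing_all_genes_errors(self, rng):
        with pytest.raises(ValueError, match="no gene of set"):
            scoring.mean_signature_score(_frame(rng), GeneSet("s", ["NOPE"]))


def _brute_recovery_auc(values, genes, set_genes, top_fraction):
    """Independent loop: rank by (-value, name), walk ranks, accumulate hits."""
    import math

    order = sorted(range(len(genes)), key=lambda j: (-values[j], genes[j]))
    k = math.ceil(top_fraction * len(genes))
    s = len(set_genes)
    hits = 0
    area = 0
    for r in range(k):
        if genes[order[r]] in set_genes:
            hits += 1
        area += hits
    max_area = sum(min(r + 1, s) for r in range(k))
    return area / max_area


class TestRecoveryAUC:
    def test_set_at_top_ranks_saturates(self):
        genes = [f"G{j:02d}" for j in range(50)]
        values = np.arange(50, 0, -1, dtype=float)
        df = pd.DataFrame([values], columns=genes)
        score = scoring.auc_recovery_score(df, GeneSet("s", genes[:5]), top_fraction=0.2)
        assert score.iloc[0] == pytest.approx(1.0)

    def test_set_outside_window_scores_zero(self):
        genes = [f"G{j:02d}" for j in range(50)]
        values = np.arange(50, 0, -1, dtype=float)
        df = pd.DataFrame([values], columns=genes)
        score = scoring.auc_recovery_score(df, GeneSet("s", genes[-5:]), top_fraction=0.2)
        assert score.iloc[0] == 0.0

    def test_matches_brute_force_oracle_on_random_sets(self, rng):
        genes = [f"G{j:02d}" for j in range(50)]
        df = pd.DataFrame(rng.exponential(1.0, size=(20, 50)), columns=genes)
        for _ in range(10):
            sub = list(rng.choice(genes, size=5, replace=False))
            score = scoring.auc_recovery_score(df, GeneSet("s", sub), top_fraction=0.2)
            for i in range(20):
                exp = _brute_recovery_auc(df.iloc[i].to_numpy(), genes, set(sub), 0.2)
                assert score.iloc[i] == pytest.approx(exp, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        df = _frame(rng, n_cells=15, n_genes=40)
        gs = GeneSet("s", list(df.columns[::7]))
        s1 = scoring.auc_recovery_score(df, gs, top_fraction=0.25)
        s2 = scoring.auc_recovery_score(np.expm1(df) + 3.0, gs, top_fraction=0.25)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_set_larger_than_universe_errors(self, rng):
        df = _frame(rng, n_genes=5)
        with pytest.raises(ValueError, match="exceeds"):
            scoring.auc_recovery_score(df, GeneSet("s", [f"X{i}" for i in range(9)]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 1.0))
    def test_scores_always_in_unit_interval(self, seed, top_fraction):
        rng = np.random.default_rng(seed)
        df = _frame(rng, n_cells=4, n_genes=30)
        gs = GeneSet("s", list(df.columns[:4]))
        s = scoring.auc_recovery_score(df, gs, top_fraction=top_fraction)
        assert ((s >= 0) & (s <= 1)).all()


def test_planted_overexpression_ranks_cells_by_both_engines(rng):
    """Cells over-expressing a set separate from background (AUROC >= 0.9)."""
    from sklearn.metrics import roc_auc_score

    df = _frame(rng, n_cells=200, n_genes=100)
    hot = np.zeros(200, dtype=bool)
    hot[:60] = True
    sig = list(df.columns[:8])
    df.loc[hot, sig] += 2.0 * df[sig].to_numpy().std()
    gs = GeneSet("s", sig)
    for engine in (scoring.mean_signature_score, scoring.auc_recovery_score):
        score = engine(df, gs)
        assert roc_auc_score(hot, score) >= 0.9


class TestRegulons:
    def _activity(self, fractions, n_cells=100, cutoff=0.2):
        regs = [f"R{i}" for i in fractions]
        auc = pd.DataFrame(0.0, index=[f"c{i}" for i in range(n_cells)], columns=regs)
        for i, f in fractions.items():
            auc.iloc[: int(round(f * n_cells)), list(fractions).index(i)] = 0.9
        return RegulonActivity(auc=auc, global_cutoff=cutoff)

    def test_binary_matches_cutoff_definition(self, rng):
        auc = pd.DataFrame(rng.uniform(size=(30, 4)), columns=list("ABCD"))
        cut = pd.Series([0.3, 0.5, 0.7, 0.2], index=list("ABCD"))
        act = RegulonActivity(auc=auc, cutoffs=cut)
        assert ((act.binary == 1) == (auc >= cut)).all().all()

    def test_thresholds_by_cluster_type(self):
        act = self._activity({0: 0.21, 1: 0.45, 2: 0.20})
        annot = pd.Series("tumor", index=act.auc.index)
        table = scoring.significant_regulons(act, annot)
        by_reg = table.set_index("regulon").significant
        assert by_reg["R0"]  # 21% > 20%
        assert by_reg["R1"]
        assert not by_reg["R2"]  # exactly 20% is not "more than 20%"
        stromal = scoring.significant_regulons(act, pd.Series("caf", index=act.auc.index), {"caf"})
        assert not stromal.set_index("regulon").significant["R1"]  # 45% <= 50%

    def test_unannotated_cells_error(self):
        act = self._activity({0: 0.5})
        annot = pd.Series("x", index=act.auc.index[:-5])
        with pytest.raises(ValueError, match="missing"):
            scoring.significant_regulons(act, annot)


def test_gmt_roundtrip(tmp_path):
    sets = [GeneSet("a", ["X", "Y"], "d1"), GeneSet("b", ["Z"], "d2")]
    path = tmp_path / "x.gmt"
    scoring.write_gmt(sets, path)
    back = scoring.read_gmt(path)
    assert [(s.name, s.genes) for s in back] == [("a", ["X", "Y"]), ("b", ["Z"])]


def test_shipped_signatures_load():
    from tmecompare.datasets import curated_lr_pairs, literature_signatures

    sets = {s.name: s for s in literature_signatures()}
    assert set(sets["naiveness"].genes) == {"TCF7", "CCR7", "SELL", "LEF1"}
    pairs = curated_lr_pairs()
    assert {"pair_id", "ligand", "receptor"} <= set(pairs.columns)
    assert (pairs.receptor == "TGFBR1,TGFBR2").sum() == 3
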