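import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oracles import bh_stepup
from tallfusion import synthetic_data as sd
from tallfusion.core_io import CountsMatrix, GeneSet
from tallfusion.expression_signatures import (
    QCThresholds,
    correlate_with_gene,
    derive_signature,
    differential_expression,
    log_normalize_cp10k,
    qc_filter_cells,
    rank_genes,
    score_signature_bulk,
    score_signature_cells,
    tpm_normalize,
)


def matrix_from(values: dict, lengths: dict | None = None) -> CountsMatrix:
    df = pd.DataFrame(values)
    lengths_s = pd.Series(lengths) if lengths else None
    return CountsMatrix(values=df, gene_lengths=lengths_s)


class TestTPM:
    def test_two_gene_closed_form(self):
        m = matrix_from({"s1": {"g1": 10, "g2": 10}}, {"g1": 1000, "g2": 2000})
        tpm = tpm_normalize(m).values["s1"]
        assert tpm["g1"] == pytest.approx(2e6 / 3)
        assert tpm["g2"] == pytest.approx(1e6 / 3)

    def test_single_gene_gets_the_whole_million(self):
        m = matrix_from({"s1": {"g1": 7}}, {"g1": 500})
        assert tpm_normalize(m).values.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_a_million(self, rng):
        counts = rng.integers(0, 1000, size=(50, 8))
        genes = [f"g{i}" for i in range(50)]
        m = CountsMatrix(
            values=pd.DataFrame(counts, index=genes,
                                columns=[f"s{j}" for j in range(8)]),
            gene_lengths=pd.Series(rng.integers(200, 5000, 50), index=genes),
        )
        np.testing.assert_allclose(tpm_normalize(m).values.sum(axis=0), 1e6)

    def test_zero_count_sample_left_as_zeros(self, caplog):
        m = matrix_from({"s1": {"g1": 10, "g2": 5}, "s2": {"g1": 0, "g2": 0}},
                        {"g1": 1000, "g2": 1000})
        with caplog.at_level("WARNING"):
            tpm = tpm_normalize(m)
        assert (tpm.values["s2"] == 0).all()

    def test_lengths_required(self):
        with pytest.raises(ValueError, match="lengths"):
            tpm_normalize(matrix_from({"s1": {"g1": 1}}))


class TestQC:
    def make_cells(self, n_genes=300):
        genes = [f"MT-{i}" for i in range(5)] + [f"RP{i}" for i in range(5)] + [
            f"g{i}" for i in range(n_genes - 10)
        ]
        good = pd.Series(1, index=genes)
        return genes, good

    def test_boundary_fractions_follow_strict_comparisons(self):
        # a cell with mito fraction exactly 0.1 is kept (rule is ">0.1"):
        # 10 mitochondrial reads out of 100 total
        genes, _ = self.make_cells()
        mito, ribo = genes[:5], genes[5:10]
        other_genes = genes[10:]
        cell = pd.Series(0, index=genes)
        cell[mito] = 2                # 10 mitochondrial reads
        cell[other_genes[:90]] = 1    # 90 other reads; 95 expressed genes
        m = matrix_from({"boundary": cell, "ok": pd.Series(1, index=genes)})
        kept, qc = qc_filter_cells(m, mito, ribo, QCThresholds(min_genes=10))
        row = qc.set_index("cell_id").loc["boundary"]
        assert row["mito_fraction"] == pytest.approx(10 / 100)
        assert row["kept"]

    def test_low_gene_count_cell_dropped(self):
        genes, _ = self.make_cells()
        sparse = pd.Series(0, index=genes)
        sparse[genes[10:209]] = 1  # 199 expressed genes
        dense = pd.Series(1, index=genes)  # 300 expressed genes
        m = matrix_from({"sparse": sparse, "dense": dense})
        kept, qc = qc_filter_cells(m, genes[:5], genes[5:10])
        assert kept == ["dense"]
        assert not qc.set_index("cell_id").loc["sparse", "kept"]

    def test_all_pass_matrix_keeps_everything(self):
        genes, _ = self.make_cells()
        m = matrix_from({f"c{i}": pd.Series(1, index=genes) for i in range(5)})
        kept, _ = qc_filter_cells(m, genes[:5], genes[5:10])
        assert len(kept) == 5

    def test_high_ribo_cell_dropped(self):
        genes, _ = self.make_cells()
        ribo_heavy = pd.Series(1, index=genes)
        ribo_heavy[genes[5:10]] = 200  # ribo fraction 1000/1290 > 0.6
        m = matrix_from({"bad": ribo_heavy, "ok": pd.Series(1, index=genes)})
        kept, _ = qc_filter_cells(m, genes[:5], genes[5:10], QCThresholds(min_genes=10))
        assert kept == ["ok"]


class TestDifferentialExpression:
    def test_constant_gene_has_null_statistics(self):
        # the varying pair keeps per-sample totals constant so the flat
        # gene stays constant after CPM normalization too
        values = pd.DataFrame(
            {f"s{i}": {"flat": 10, "var": 5 + i, "anti": 20 - i} for i in range(6)}
        )
        de = differential_expression(values, [f"s{i}" for i in range(3)],
                                     [f"s{i}" for i in range(3, 6)])
        flat = de.set_index("gene").loc["flat"]
        assert flat["log2_fold_change"] == pytest.approx(0.0, abs=1e-9)
        assert flat["p_value"] == 1.0

    def test_null_data_yields_few_discoveries(self):
        fractions = []
        for seed in range(3):
            m, truth = sd.simulate_expression(8, 8, n_genes=400, n_signature_up=0,
                                              n_signature_down=0, log2_effect=0.0,
                                              seed=seed)
            de = differential_expression(m, truth.params["groupA"], truth.params["groupB"])
            fractions.append((de["adjusted_p"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05

    def test_planted_effects_recovered_with_high_power(self):
        m, truth = sd.simulate_expression(10, 10, n_genes=1000, n_signature_up=40,
                                          n_signature_down=40, log2_effect=2.0,
                                          dispersion=0.05, seed=17)
        de = differential_expression(m, truth.params["groupA"], truth.params["groupB"])
        planted = truth.records.query("is_signature")["gene"]
        hits = de.set_index("gene").loc[planted, "adjusted_p"] < 0.05
        assert hits.mean() >= 0.90

    def test_small_groups_rejected(self):
        values = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["g"])
        with pytest.raises(ValueError, match=">= 2"):
            differential_expression(values, ["a"], ["b", "c"])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    def test_bh_adjustment_matches_stepup_reference(self, pvals):
        np.testing.assert_allclose(
            multipletests(pvals, method="fdr_bh")[1], bh_stepup(pvals), rtol=1e-12
        )


class TestDeriveSignature:
    def make_de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p_value", "adjusted_p"])

    def test_empty_table_gives_empty_sides(self):
        up, down = derive_signature(self.make_de([]))
        assert up is None and down is None

    def test_fold_change_threshold_is_strict(self):
        de = self.make_de([
            ("at_two", 1.0, 0.001, 0.001),        # FC exactly 2 -> excluded
            ("above", 1.3, 0.001, 0.001),
            ("below", -1.3, 0.001, 0.001),
            ("not_sig", 3.0, 0.5, 0.9),
        ])
        up, down = derive_signature(de)
        assert set(up.genes) == {"above"}
        assert set(down.genes) == {"below"}

    def test_recovers_planted_signature(self):
        m, truth = sd.simulate_expression(10, 10, n_genes=1000, n_signature_up=40,
                                          n_signature_down=40, log2_effect=2.0,
                                          dispersion=0.05, seed=23)
        de = differential_expression(m, truth.params["groupA"], truth.params["groupB"])
        up, _ = derive_signature(de)
        planted_up = set(truth.records.query("direction == 1")["gene"])
        found = set(up.genes)
        jaccard = len(found & planted_up) / len(found | planted_up)
        assert jaccard >= 0.8


class TestBulkScoring:
    def test_two_sample_single_gene_pinned_value(self):
        # one gene with values (1, 3): sample-SD z-scores are -/+ 0.7071,
        # and rescaling the (single-gene) means reproduces -/+ 0.7071
        values = pd.DataFrame({"s1": {"g": 1.0}, "s2": {"g": 3.0}})
        scores = score_signature_bulk(values, GeneSet("S", "", ("g",)))
        np.testing.assert_allclose(
            scores["score"].to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)], rtol=1e-12
        )

    def test_rescaled_scores_standardized(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(12)],
        ) + 5
        scores = score_signature_bulk(values, GeneSet("S", "", tuple(f"g{i}" for i in range(10))))
        assert scores["score"].mean() == pytest.approx(0.0, abs=1e-12)
        assert scores["score"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_invariant_to_affine_per_gene_transforms(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(8)],
        )
        gs = GeneSet("S", "", tuple(f"g{i}" for i in range(8)))
        base = score_signature_bulk(values, gs)["score"]
        scale = pd.Series(rng.uniform(0.5, 4, 20), index=values.index)
        shift = pd.Series(rng.normal(0, 10, 20), index=values.index)
        transformed = values.mul(scale, axis=0).add(shift, axis=0)
        np.testing.assert_allclose(
            score_signature_bulk(transformed, gs)["score"], base, rtol=1e-9
        )

    def test_constant_gene_dropped_with_warning(self, caplog):
        values = pd.DataFrame(
            {"s1": {"g1": 1.0, "flat": 2.0}, "s2": {"g1": 3.0, "flat": 2.0}}
        )
        with caplog.at_level("WARNING"):
            scores = score_signature_bulk(values, GeneSet("S", "", ("g1", "flat")))
        assert "constant" in caplog.text
        assert len(scores) == 2

    def test_signature_separates_planted_groups(self):
        m, truth = sd.simulate_expression(10, 10, n_genes=800, n_signature_up=30,
                                          n_signature_down=30, log2_effect=2.0,
                                          dispersion=0.05, seed=29)
        up = GeneSet("up", "", tuple(truth.records.query("direction == 1")["gene"]))
        scores = score_signature_bulk(m.values, up).set_index("sample_id")["score"]
        assert scores[truth.params["groupA"]].mean() > scores[truth.params["groupB"]].mean()

    def test_missing_signature_is_an_error(self):
        values = pd.DataFrame({"s1": {"g": 1.0}, "s2": {"g": 2.0}})
        with pytest.raises(ValueError, match="no genes present"):
            score_signature_bulk(values, GeneSet("S", "", ("absent",)))


class TestCellScoring:
    @pytest.fixture()
    def cells(self, rng):
        n_genes, n_cells = 400, 120
        counts = rng.negative_binomial(5, 0.3, size=(n_genes, n_cells)).astype(float)
        sig_genes = [f"g{i}" for i in range(12)]
        counts[:12, :40] *= 6  # planted high-signature cells
        values = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"c{j}" for j in range(n_cells)])
        return log_normalize_cp10k(values), sig_genes

    def test_deterministic_under_seed(self, cells):
        logn, sig = cells
        gs = GeneSet("S", "", tuple(sig))
        s1 = score_signature_cells(logn, gs, seed=3)
        s2 = score_signature_cells(logn, gs, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_random_gene_set_scores_centre_at_zero(self, rng):
        values = pd.DataFrame(
            rng.negative_binomial(5, 0.3, size=(300, 80)).astype(float),
            index=[f"g{i}" for i in range(300)],
            columns=[f"c{j}" for j in range(80)],
        )
        logn = log_normalize_cp10k(values)
        gs = GeneSet("R", "", tuple(rng.choice(logn.index, 15, replace=False)))
        scores = score_signature_cells(logn, gs, seed=5)
        # raw (pre-z) score of an expression-matched random set is ~0
        assert abs(scores["raw_score"].mean()) < 0.1

    def test_planted_cells_score_higher(self, cells):
        logn, sig = cells
        scores = score_signature_cells(logn, GeneSet("S", "", tuple(sig)), seed=7)
        planted = scores.iloc[:40]["score"].mean()
        background = scores.iloc[40:]["score"].mean()
        assert planted > background + 1.0

    def test_needs_enough_genes_for_bins(self, cells):
        logn, sig = cells
        with pytest.raises(ValueError, match="bins"):
            score_signature_cells(logn.iloc[:10], GeneSet("S", "", tuple(sig)))


class TestRankGenes:
    def test_plug_in_values_and_order(self):
        de = pd.DataFrame(
            {
                "gene": ["up", "down", "null"],
                "log2_fold_change": [1.5, -2.0, 0.0],
                "p_value": [0.01, 0.01, 0.8],
                "adjusted_p": [0.01, 0.01, 0.9],
            }
        )
        ranked = rank_genes(de)
        assert list(ranked["gene"]) == ["up", "null", "down"]
        scores = ranked.set_index("gene")["score"]
        assert scores["up"] == pytest.approx(2.0)
        assert scores["down"] == pytest.approx(-2.0)
        assert scores["null"] == 0.0

    def test_zero_padj_clipped_with_warning(self, caplog):
        de = pd.DataFrame(
            {"gene": ["g"], "log2_fold_change": [1.0], "p_value": [0.0], "adjusted_p": [0.0]}
        )
        with caplog.at_level("WARNING"):
            ranked = rank_genes(de)
        assert np.isfinite(ranked["score"]).all()

    def test_ties_broken_by_gene_id(self):
        de = pd.DataFrame(
            {"gene": ["b", "a"], "log2_fold_change": [1.0, 1.0],
             "p_value": [0.1, 0.1], "adjusted_p": [0.1, 0.1]}
        )
        assert list(rank_genes(de)["gene"]) == ["a", "b"]


class TestCorrelation:
    def test_identical_and_inverted_genes(self, rng):
        anchor = rng.normal(size=50)
        values = pd.DataFrame(
            [anchor, anchor, -anchor, rng.normal(size=50)],
            index=["anchor", "same", "opposite", "noise"],
            columns=[f"c{i}" for i in range(50)],
        )
        r, top, bottom = correlate_with_gene(values, "anchor", k=1)
        assert r["same"] == pytest.approx(1.0)
        assert r["opposite"] == pytest.approx(-1.0)
        assert top == ["same"]
        assert bottom == ["opposite"]
        assert "anchor" not in r.index

    def test_independent_gene_has_small_correlation(self, rng):
        n = 500
        values = pd.DataFrame(
            [rng.normal(size=n), rng.normal(size=n)],
            index=["anchor", "independent"],
            columns=[f"c{i}" for i in range(n)],
        )
        r, _, _ = correlate_with_gene(values, "anchor")
        assert abs(r["independent"]) < 0.15

    def test_constant_anchor_rejected(self):
        values = pd.DataFrame(
            {"c1": {"anchor": 1.0, "g": 2.0}, "c2": {"anchor": 1.0, "g": 3.0}}
        )
        with pytest.raises(ValueError, match="constant"):
            correlate_with_gene(values, "anchor")
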