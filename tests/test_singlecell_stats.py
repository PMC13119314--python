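import numpy as np
import pandas as pd
import pytest

from oracles import oracle_qc

from rlpkit import SimulationTruth, simulate_cells
from rlpkit.singlecell_stats import (
    CellMatrices, bin_rates, chisq_gof, detection_rate_analysis,
    detection_rates, occurrence_overlap, qc_filter_cells, shuffle_null,
)


def matrices(edits, expr=None, phase=None):
    edits = np.asarray(edits, dtype=np.int64)
    n_cells, n_genes = edits.shape
    if expr is None:
        expr = np.full((n_cells, n_genes), 1e6 / n_genes)
    return CellMatrices(
        cells=[f"c{i}" for i in range(n_cells)],
        genes=[f"g{j}" for j in range(n_genes)],
        edits=edits, expr=np.asarray(expr, dtype=float), phase=phase,
    )


def random_matrices(rng, n_cells, n_genes, max_edits=10):
    expr = rng.lognormal(3, 1, size=(n_cells, n_genes))
    expr = expr / expr.sum(axis=1, keepdims=True) * 1e6
    edits = rng.integers(0, max_edits, size=(n_cells, n_genes))
    return matrices(edits, expr)


class TestCellMatrices:
    def test_tpm_rows_must_sum_to_million(self):
        with pytest.raises(ValueError, match="TPM"):
            matrices([[0, 0]], expr=[[10.0, 10.0]])

    def test_edits_must_be_integers(self):
        with pytest.raises(ValueError, match="integer"):
            CellMatrices(cells=["c"], genes=["g", "h"],
                         edits=np.zeros((1, 2)) + 0.5,
                         expr=np.array([[5e5, 5e5]]))


class TestQCFilter:
    def test_min_genes_boundary(self):
        """8,999 detected genes removed; 9,000 kept (with a tiny min_genes
        stand-in of 3 genes to keep the fixture small)."""
        expr = np.array([
            [5e5, 5e5, 0.0, 0.0],   # 2 detected -> removed
            [25e4, 25e4, 25e4, 25e4],
            [25e4, 25e4, 25e4, 25e4],
            [25e4, 25e4, 25e4, 25e4],
            [25e4, 25e4, 25e4, 25e4],
        ])
        m = matrices(np.zeros((5, 4), dtype=int) + 3, expr)
        passing, records = qc_filter_cells(m, "NES", min_genes=3)
        assert [r.reason for r in records if not r.passed] == ["min_genes"]
        assert len(passing.cells) == 4

    def test_erm_floor(self):
        # cell 0: 150 genes with >=3 edits -> below the 200 floor
        edits = np.zeros((5, 400), dtype=int)
        edits[0, :150] = 3
        edits[1:, :250] = 3
        m = matrices(edits)
        passing, records = qc_filter_cells(m, "ERM", min_genes=0)
        assert records[0].reason == "min_edited_genes"
        assert len(passing.cells) == 4

    def test_nes_iqr_fence_worked_example(self):
        """edited_genes {100,200,300,400,5000}: Q1=200, Q3=400, upper fence
        700 -> only the 5000-cell removed."""
        edits = np.zeros((5, 5000), dtype=int)
        for i, n in enumerate([100, 200, 300, 400, 5000]):
            edits[i, :n] = 3
        m = matrices(edits)
        passing, records = qc_filter_cells(m, "NES", min_genes=0)
        assert [r.cell_id for r in records if not r.passed] == ["c4"]
        assert records[4].reason == "edited_genes_outlier"

    def test_cell_on_fence_kept(self):
        # values {0,100,200,300,700}: Q3+1.5*IQR = 300+1.5*200 = 600;
        # exactly 600 must be kept
        edits = np.zeros((5, 1000), dtype=int)
        for i, n in enumerate([0, 100, 200, 300, 600]):
            edits[i, :n] = 3
        m = matrices(edits)
        _, records = qc_filter_cells(m, "NES", min_genes=0)
        assert all(r.passed for r in records)

    def test_gene_retention_by_read_support(self):
        edits = np.zeros((4, 3), dtype=int)
        expr = np.full((4, 3), 1e6 / 3)
        support = np.array([[5, 5, 1], [5, 0, 1], [5, 5, 0], [5, 5, 1]])
        m = matrices(edits, expr)
        passing, _ = qc_filter_cells(m, "NES", min_genes=0,
                                     read_support=support)
        # gene g2 supported by >=5 reads in zero cells -> dropped
        assert passing.genes == ["g0", "g1"]
        assert np.allclose(passing.expr.sum(axis=1), 1e6)

    def test_too_few_cells_is_error(self):
        m = matrices(np.zeros((3, 2), dtype=int))
        with pytest.raises(ValueError, match="quartiles"):
            qc_filter_cells(m, "NES", min_genes=0)

    @pytest.mark.parametrize("mode", ["NES", "ERM"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_fences(self, mode, seed):
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(6, 50))
        m = random_matrices(rng, n_cells, 600)
        er = rng.uniform(0.5, 1.0, size=n_cells) if mode == "NES" else None
        min_genes = int(rng.integers(0, 400))
        detected = (m.expr > 0).sum(axis=1)
        edited = (m.edits >= 3).sum(axis=1)
        try:
            expected = oracle_qc(detected, edited, mode, min_genes,
                                 editing_ratio=er, erm_floor=5)
        except ValueError:
            with pytest.raises(ValueError):
                qc_filter_cells(m, mode, min_genes=min_genes, editing_ratio=er,
                                erm_min_edited_genes=5)
            return
        passing, _ = qc_filter_cells(m, mode, min_genes=min_genes,
                                     editing_ratio=er, erm_min_edited_genes=5)
        assert passing.cells == [m.cells[i] for i in np.flatnonzero(expected)]


class TestDetectionRates:
    def test_counting(self):
        edits = np.zeros((10, 3), dtype=int)
        edits[:4, 0] = 3       # 4 of 10 cells
        edits[:, 1] = 2        # never reaches 3
        edits[:, 2] = 7        # all cells
        r = detection_rates(matrices(edits))
        assert r.tolist() == [0.4, 0.0, 1.0]

    def test_binning_rules(self):
        edges, counts, n_zero = bin_rates(np.array([0.05, 0.05, 0.95, 0.0]))
        assert counts[0] == 2 and counts[9] == 1 and n_zero == 1
        # boundary: 0.1 goes to bin 2, 1.0 to the closed top bin
        _, counts, _ = bin_rates(np.array([0.1, 1.0]))
        assert counts[1] == 1 and counts[9] == 1
        assert counts.sum() == 2


class TestShuffleNull:
    def test_single_gene_cell_conserves_everything(self):
        expr = np.array([[1e6, 0.0], [0.0, 1e6]])
        edits = np.array([[7, 0], [0, 4]])
        m = matrices(edits, expr)
        _, _, hists = shuffle_null(m, n_shuffles=2, seed=1)
        # with expression confined to one gene per cell, simulated edits land
        # exactly where the observed ones are: each gene detected in 1 of 2
        # cells, so both genes fall in the [0.5, 0.6) bin
        for h in hists:
            assert h[5] == 2 and h.sum() == 2

    def test_per_cell_totals_conserved_and_retention_rule(self):
        rng = np.random.default_rng(0)
        m = random_matrices(rng, 8, 40)
        totals = m.edits.sum(axis=1)
        root = np.random.SeedSequence(5)
        # re-derive one shuffle by brute force from the same substream
        child = root.spawn(1)[0]
        rng2 = np.random.default_rng(child)
        sim = np.vstack([
            rng2.multinomial(int(totals[c]), m.expr[c] / m.expr[c].sum())
            for c in range(8)
        ])
        assert (sim.sum(axis=1) == totals).all()
        retained = (sim >= 3).any(axis=0)
        rates = (sim[:, retained] >= 3).mean(axis=0)
        _, counts, _ = bin_rates(rates)
        mean, _, hists = shuffle_null(m, n_shuffles=1, seed=5)
        assert (hists[0] == counts).all()

    def test_zero_tpm_cell_is_error(self):
        m = matrices(np.zeros((2, 2), dtype=int))
        # the TPM invariant normally excludes this; corrupt in place to
        # exercise the guard
        m.expr[1] = 0.0
        with pytest.raises(ValueError, match="zero total TPM"):
            shuffle_null(m)

    def test_uniform_tpm_matches_binomial_moments(self):
        """Uniform TPM over G genes, N edits per cell: per-gene simulated
        edit counts match Binomial(N, 1/G) moments within 3 SE."""
        G, N, n_cells = 20, 60, 1000
        edits = np.zeros((n_cells, G), dtype=int)
        edits[:, 0] = N
        m = matrices(edits)
        root = np.random.SeedSequence(9)
        rng = np.random.default_rng(root.spawn(1)[0])
        sim = np.vstack([rng.multinomial(N, np.full(G, 1 / G))
                         for _ in range(n_cells)])
        p = 1 / G
        mean_se = np.sqrt(N * p * (1 - p) / n_cells)
        assert abs(sim[:, 3].mean() - N * p) < 3 * mean_se
        var = sim[:, 3].var(ddof=1)
        var_se = N * p * (1 - p) * np.sqrt(2 / (n_cells - 1))
        assert abs(var - N * p * (1 - p)) < 3 * var_se


class TestChisqGof:
    def test_identity_gives_zero(self):
        stat, df, p, merged = chisq_gof(np.array([10.0, 20.0]),
                                        np.array([10.0, 20.0]))
        assert stat == 0.0 and p == pytest.approx(1.0) and df == 1

    def test_hand_worked_example(self):
        stat, df, p, _ = chisq_gof(np.array([8.0, 2.0]), np.array([5.0, 5.0]))
        assert stat == pytest.approx(3.6)
        assert df == 1

    def test_rescaling_of_expected(self):
        # expected rescaled to observed total before the statistic
        stat, _, _, _ = chisq_gof(np.array([8.0, 2.0]), np.array([50.0, 50.0]))
        assert stat == pytest.approx(3.6)

    def test_empty_bin_merged(self):
        obs = np.array([0.0, 10.0, 10.0])
        exp = np.array([0.0, 10.0, 10.0])
        stat, df, p, merged = chisq_gof(obs, exp)
        assert merged and df == 1 and stat == 0.0


class TestHeterogeneityDetection:
    def test_null_data_not_rejected_typically(self):
        rejections = 0
        for i in range(20):
            truth = SimulationTruth(seed=500 + i, n_genes=300, n_cells=50,
                                    core_fraction=0, rare_fraction=0)
            m, _ = simulate_cells(truth)
            res = detection_rate_analysis(m, seed=600 + i)
            rejections += res.pvalue < 0.05
        assert rejections <= 3

    def test_planted_heterogeneity_rejected(self):
        truth = SimulationTruth(seed=700, n_genes=300, n_cells=50,
                                core_fraction=0, rare_fraction=0,
                                hetero_fraction=0.2)
        m, _ = simulate_cells(truth)
        res = detection_rate_analysis(m, seed=701)
        assert res.pvalue < 0.05

    def test_core_and_rare_rates_match_truth(self):
        truth = SimulationTruth(seed=800, n_genes=200, n_cells=200)
        m, t = simulate_cells(truth)
        rates = detection_rates(m)
        roles = pd.Series(t["roles"])
        core = rates[roles[roles == "core"].index]
        rare = rates[roles[roles == "rare"].index]
        # binomial 3-SE band around the membership probabilities
        se = np.sqrt(0.95 * 0.05 / 200)
        assert np.allclose(core, 0.95, atol=3 * se + 1e-9)
        assert (rare < 0.1 + 3 * se).all()


class TestOccurrenceOverlap:
    def test_superset_and_disjoint(self):
        rates = pd.Series({"a": 0.15, "b": 0.55, "c": 0.95})
        full = occurrence_overlap(rates, {"a", "b", "c"})
        assert full.dropna().fraction_overlap.eq(1.0).all()
        none = occurrence_overlap(rates, {"x"})
        assert none.dropna().fraction_overlap.eq(0.0).all()

    def test_hand_computed_fractions(self):
        rates = pd.Series({"a": 0.05, "b": 0.07, "c": 0.55})
        out = occurrence_overlap(rates, {"a", "c"})
        assert out.loc[0, "fraction_overlap"] == pytest.approx(0.5)
        assert out.loc[5, "fraction_overlap"] == pytest.approx(1.0)
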