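"""Fisher exact test, Bonferroni adjustment, module enumeration and the runner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from conftest import toy_matrix
from fisher_oracle import fisher_two_sided_oracle
from metamod.cohort_io import EARLY_PRIMARY, METASTATIC
from metamod.enrichment import (
    ContingencyTable,
    EnrichmentConfig,
    GeneModule,
    bonferroni_adjust,
    enumerate_modules,
    fisher_exact_two_sided,
    haldane_odds_ratio,
    module_carrier_count,
    run_enrichment,
    select_driver_genes,
)


class TestFisher:
    def test_symmetric_extreme_table(self):
        # both extreme tables with margins (5,5)/(5,5) have probability 1/252
        p, _ = fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, abs=1e-15)

    def test_degenerate_margin_gives_p_one(self):
        p, orr = fisher_exact_two_sided(ContingencyTable(0, 10, 0, 10))
        assert p == 1.0
        assert orr == 1.0  # Haldane correction keeps the ratio defined

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_matches_exact_oracle_on_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 8, size=4)
            p, _ = fisher_exact_two_sided(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-12)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_scipy_two_sided(self, cells):
        a, b, c, d = cells
        p, _ = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        p_ref = scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue
        assert p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_large_single_tail_table(self):
        # carrier counts of the melanoma worked example: 14/1148 vs 0/669
        p, orr = fisher_exact_two_sided(ContingencyTable(14, 1134, 0, 669))
        assert p == pytest.approx(fisher_two_sided_oracle(14, 1134, 0, 669), rel=1e-10)
        assert orr > 1  # metastatic-enriched

    def test_haldane_correction_only_on_zero_cells(self):
        assert haldane_odds_ratio(ContingencyTable(2, 3, 4, 5)) == pytest.approx(10 / 12)
        assert haldane_odds_ratio(ContingencyTable(2, 3, 0, 5)) == pytest.approx(
            (2.5 * 5.5) / (3.5 * 0.5)
        )


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni_adjust([0.001], 50) == [pytest.approx(0.05)]
        assert bonferroni_adjust([0.5], 10) == [1.0]

    def test_melanoma_printed_pair(self):
        # q = min(1, P*m) with m = 161 turns P = 0.00097 into ~0.156
        q = bonferroni_adjust([0.00097], 161)[0]
        assert q == pytest.approx(0.156, abs=5e-4)

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1], 0)

    def test_q_monotone_in_family_size(self):
        p = [0.004]
        qs = [bonferroni_adjust(p, m)[0] for m in (1, 10, 100, 1000)]
        assert qs == sorted(qs)
        assert all(q >= p[0] for q in qs)


class TestModules:
    @pytest.mark.parametrize(
        "genes,max_size,expected",
        [
            (["A", "B", "C"], 2, 6),
            (["A"], 3, 1),
            ([f"G{i}" for i in range(10)], 3, 175),
        ],
    )
    def test_enumeration_counts(self, genes, max_size, expected):
        modules = enumerate_modules(genes, max_size)
        assert len(modules) == expected
        assert len(set(modules)) == expected  # no duplicates

    def test_module_canonical_identity(self):
        assert GeneModule(["TP53", "APC"]) == GeneModule(["APC", "TP53", "APC"])
        assert GeneModule(["APC", "PTPRT", "TP53"]).name == "APC-PTPRT-TP53"

    def test_carrier_count_uses_and_semantics(self):
        matrix = toy_matrix(
            [[1, 1], [1, 0], [0, 1], [1, 1]],
            ["M", "M", "E", "E"],
            genes=["APC", "TP53"],
        )
        both = GeneModule(["APC", "TP53"])
        assert module_carrier_count(matrix, both, METASTATIC) == 1
        assert module_carrier_count(matrix, both, EARLY_PRIMARY) == 1
        assert module_carrier_count(matrix, GeneModule(["APC"]), METASTATIC) == 2

    def test_carrier_count_unknown_gene_named_in_error(self):
        matrix = toy_matrix([[1]], ["M"], genes=["APC"])
        with pytest.raises(KeyError, match="KRAS"):
            module_carrier_count(matrix, GeneModule(["KRAS"]), METASTATIC)

    def test_carrier_monotone_in_module_size(self):
        rng = np.random.default_rng(5)
        matrix = toy_matrix(
            rng.random((30, 4)) < 0.4, ["M"] * 15 + ["E"] * 15
        )
        genes = matrix.genes
        for cohort in (METASTATIC, EARLY_PRIMARY):
            for k in range(1, 4):
                small = module_carrier_count(matrix, GeneModule(genes[:k]), cohort)
                large = module_carrier_count(matrix, GeneModule(genes[: k + 1]), cohort)
                assert large <= small


class TestDriverSelection:
    def test_threshold_boundary(self):
        # gene A in 5 metastatic carriers (kept), gene B in 4 (dropped)
        ind = np.zeros((12, 2), dtype=bool)
        ind[:5, 0] = True
        ind[:4, 1] = True
        matrix = toy_matrix(ind, ["M"] * 6 + ["E"] * 6, genes=["A", "B"])
        assert select_driver_genes(matrix, ["A", "B"], min_met_samples=5) == ["A"]

    def test_non_driver_genes_ignored(self):
        ind = np.ones((10, 2), dtype=bool)
        matrix = toy_matrix(ind, ["M"] * 5 + ["E"] * 5, genes=["A", "B"])
        assert select_driver_genes(matrix, ["A"], min_met_samples=5) == ["A"]

    def test_empty_driver_list_rejected(self):
        matrix = toy_matrix([[True]], ["M"], genes=["A"])
        with pytest.raises(ValueError):
            select_driver_genes(matrix, [])


class TestRunEnrichment:
    def _matrix(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        ind = rng.random((n, 3)) < 0.3
        return toy_matrix(ind, ["M"] * (n // 2) + ["E"] * (n - n // 2))

    def test_single_driver_q_equals_p(self):
        matrix = self._matrix()
        results = run_enrichment(matrix, ["G0"], EnrichmentConfig(min_met_samples=1, max_module_size=1))
        assert len(results) == 1
        assert results[0].q_value == pytest.approx(results[0].p_value)
        assert results[0].n_tests == 1

    def test_label_swap_inverts_direction_but_not_p(self):
        matrix = self._matrix(seed=3)
        swapped = toy_matrix(
            matrix.indicator,
            ["E" if matrix.cohort_of[s] == METASTATIC else "M" for s in matrix.sample_ids],
        )
        cfg = EnrichmentConfig(min_met_samples=1, max_module_size=2)
        res = {r.module.name: r for r in run_enrichment(matrix, matrix.genes, cfg)}
        res_sw = {r.module.name: r for r in run_enrichment(swapped, matrix.genes, cfg)}
        for name, r in res.items():
            assert res_sw[name].p_value == pytest.approx(r.p_value, rel=1e-12)
            if r.enriched_in in (METASTATIC, EARLY_PRIMARY):
                flipped = METASTATIC if r.enriched_in == EARLY_PRIMARY else EARLY_PRIMARY
                assert res_sw[name].enriched_in == flipped

    def test_results_sorted_and_q_valid(self):
        matrix = self._matrix(seed=7)
        results = run_enrichment(matrix, matrix.genes, EnrichmentConfig(min_met_samples=1))
        keys = [(r.q_value, r.p_value, len(r.module), r.module.genes) for r in results]
        assert keys == sorted(keys)
        for r in results:
            assert 0 < r.p_value <= 1
            assert r.p_value <= r.q_value <= 1
            assert r.q_value == pytest.approx(min(1.0, r.p_value * r.n_tests))

    def test_injected_module_outranks_null_modules(self):
        # a strongly enriched pair should carry the smallest P of all modules
        from metamod.synthetic import SimConfig, matrix_from_truth, simulate_cohort

        genes = {f"G{i}": 0.08 for i in range(6)}
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                cancer_type="TOY", n_metastatic=1500, n_early=1500, genes=genes,
                enriched_modules=[(GeneModule(["G0", "G1"]), 5.0)],
                msi_h_fraction=0.0, seed=100 + seed,
            )
            _, _, truth = simulate_cohort(cfg)
            results = run_enrichment(
                matrix_from_truth(truth), list(genes), EnrichmentConfig(max_module_size=2)
            )
            best = min(results, key=lambda r: r.p_value)
            injected = next(r for r in results if r.module.name == "G0-G1")
            null_best = min(
                (r for r in results if not set(r.module.genes) & {"G0", "G1"}),
                key=lambda r: r.p_value,
            )
            if injected.enriched_in == METASTATIC and injected.p_value < null_best.p_value:
                hits += 1
        assert hits >= 19  # >= 95% of replicates

    def test_module_count_guard_rail(self):
        matrix = toy_matrix(np.ones((40, 25), dtype=bool), ["M"] * 20 + ["E"] * 20)
        cfg = EnrichmentConfig(min_met_samples=1, max_module_size=10, max_modules=1000)
        with pytest.raises(ValueError, match="force"):
            run_enrichment(matrix, matrix.genes, cfg)
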