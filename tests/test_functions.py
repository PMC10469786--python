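"""Pathway presence, enrichment, CAZyme consensus and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magtaxa import (HitEvidence, PathwayDefinition, cazyme_consensus,
                     compare_groups, enriched_modules,
                     load_pathway_definitions, pathway_presence, pul_markers)

TEN = PathwayDefinition("pw10", "ten genes", frozenset(f"K{i:05d}"
                                                       for i in range(10)))
FIVE = PathwayDefinition("pw5", "five genes", frozenset(f"K9{i:04d}"
                                                        for i in range(5)))
DEFS = {"pw10": TEN, "pw5": FIVE}


class TestPathwayPresence:
    @pytest.mark.parametrize("n_genes,expected", [(8, True), (7, False),
                                                  (10, True), (0, False)])
    def test_eighty_percent_rule_on_ten_genes(self, n_genes, expected):
        genes = set(sorted(TEN.genes)[:n_genes])
        pm = pathway_presence({"g": genes}, {"pw10": TEN})
        assert bool(pm.presence.loc["g", "pw10"]) is expected

    def test_exact_boundary_is_inclusive(self):
        genes = set(sorted(FIVE.genes)[:4])  # 4/5 = 0.8 exactly
        pm = pathway_presence({"g": genes}, {"pw5": FIVE})
        assert bool(pm.presence.loc["g", "pw5"])
        assert pm.completeness.loc["g", "pw5"] == pytest.approx(0.8)

    def test_monotone_under_gene_addition(self):
        rng = np.random.default_rng(0)
        genes = set(rng.choice(sorted(TEN.genes), size=6, replace=False))
        before = pathway_presence({"g": genes}, DEFS).presence
        extra = genes | set(rng.choice(sorted(TEN.genes | FIVE.genes), size=8,
                                       replace=False))
        after = pathway_presence({"g": extra}, DEFS).presence
        assert (after | ~before).all(axis=None)  # present never flips off

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            PathwayDefinition("empty", "none", frozenset())
        with pytest.raises(ValueError):
            pathway_presence({"g": set()}, {})

    def test_packaged_definitions_load(self):
        defs = load_pathway_definitions()
        assert "glycolysis" in defs
        assert defs["glycolysis"].size == 10
        assert all(d.size >= 1 for d in defs.values())


class TestEnrichedModules:
    @staticmethod
    def presence_frame(rows_a, rows_b):
        genomes = [f"a{i}" for i in range(len(rows_a))] + \
                  [f"b{i}" for i in range(len(rows_b))]
        groups = {g: ("A" if g.startswith("a") else "B") for g in genomes}
        df = pd.DataFrame(rows_a + rows_b, index=genomes)
        return df, groups

    def test_extreme_separation_is_enriched(self):
        df, groups = self.presence_frame([{"m1": True}] * 20,
                                         [{"m1": False}] * 20)
        out = enriched_modules(df, groups)
        assert bool(out.loc["m1", "enriched"])
        assert out.loc["m1", "q_value"] < 1e-6
        assert out.loc["m1", "prevalence_A"] == 100.0
        assert out.loc["m1", "prevalence_B"] == 0.0

    def test_equal_prevalence_not_enriched(self):
        rows = [{"m1": i < 10} for i in range(20)]
        df, groups = self.presence_frame(rows, rows)
        out = enriched_modules(df, groups)
        assert not out["enriched"].any()

    def test_identical_groups_never_enrich(self):
        rng = np.random.default_rng(3)
        rows = [{f"m{j}": bool(rng.random() < 0.5) for j in range(6)}
                for _ in range(15)]
        df, groups = self.presence_frame(rows, rows)
        out = enriched_modules(df, groups, q_max=0.99)
        assert not out["enriched"].any()

    def test_completeness_threshold_applied(self):
        genomes = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        groups = {g: g[0].upper() for g in genomes}
        comp = pd.DataFrame({"m1": [0.85] * 10 + [0.79] * 10}, index=genomes)
        out = enriched_modules(comp, groups, completion_threshold=0.8)
        assert out.loc["m1", "prevalence_A"] == 100.0
        assert out.loc["m1", "prevalence_B"] == 0.0

    def test_zero_genome_group_rejected(self):
        df = pd.DataFrame({"m1": [True, False]}, index=["a0", "a1"])
        with pytest.raises(ValueError):
            enriched_modules(df, {"a0": "A", "a1": "A", "ghost": "B"})

    def test_detection_rate_matches_exact_test_power(self):
        """Planted 30-point prevalence gap: empirical detection rate over
        simulations must match the brute-force power of the exact test."""
        n, p_a, p_b, q_max = 30, 0.75, 0.45, 0.01
        power = 0.0
        for ka in range(n + 1):
            for kb in range(n + 1):
                _, p = stats.fisher_exact([[ka, n - ka], [kb, n - kb]])
                if p < q_max:
                    power += (stats.binom.pmf(ka, n, p_a)
                              * stats.binom.pmf(kb, n, p_b))
        rng = np.random.default_rng(11)
        n_sim, detected = 300, 0
        for _ in range(n_sim):
            rows_a = [{"m1": bool(rng.random() < p_a)} for _ in range(n)]
            rows_b = [{"m1": bool(rng.random() < p_b)} for _ in range(n)]
            df, groups = self.presence_frame(rows_a, rows_b)
            out = enriched_modules(df, groups, q_max=q_max)
            detected += int(out["enriched"].any())
        rate = detected / n_sim
        sd = np.sqrt(power * (1 - power) / n_sim)
        assert abs(rate - power) <= 4 * sd


class TestCazymeConsensus:
    def test_both_strategies_pass(self):
        ev = HitEvidence("gene1", "GH5", a_pident=45.0, a_coverage=0.6,
                         b_evalue=1e-20, b_coverage=0.4)
        assert cazyme_consensus([ev]) == [("gene1", "GH5")]

    def test_single_strategy_rejected(self):
        ev = HitEvidence("gene1", "GH5", a_pident=45.0, a_coverage=0.6)
        assert cazyme_consensus([ev]) == []

    @pytest.mark.parametrize("kwargs", [
        dict(a_pident=39.0, a_coverage=0.6, b_evalue=1e-20, b_coverage=0.4),
        dict(a_pident=40.0, a_coverage=0.6, b_evalue=1e-20, b_coverage=0.4),
        dict(a_pident=45.0, a_coverage=0.5, b_evalue=1e-20, b_coverage=0.4),
        dict(a_pident=45.0, a_coverage=0.6, b_evalue=1e-15, b_coverage=0.4),
        dict(a_pident=45.0, a_coverage=0.6, b_evalue=1e-20, b_coverage=0.35),
    ])
    def test_strict_boundaries_reject(self, kwargs):
        assert cazyme_consensus([HitEvidence("g", "GH5", **kwargs)]) == []

    def test_evidence_rows_merge_per_gene_family(self):
        rows = [HitEvidence("g", "GH5", a_pident=50.0, a_coverage=0.8),
                HitEvidence("g", "GH5", b_evalue=1e-30, b_coverage=0.5),
                HitEvidence("g", "GH13", a_pident=50.0, a_coverage=0.8),
                HitEvidence("g", "GH13", b_evalue=1e-5, b_coverage=0.5)]
        assert cazyme_consensus(rows) == [("g", "GH5")]

    def test_output_subset_of_each_strategy(self):
        rng = np.random.default_rng(1)
        rows = [HitEvidence(f"g{i}", "GH5",
                            a_pident=float(rng.uniform(30, 60)),
                            a_coverage=float(rng.uniform(0.3, 0.9)),
                            b_evalue=float(10 ** rng.uniform(-30, -5)),
                            b_coverage=float(rng.uniform(0.2, 0.6)))
                for i in range(100)]
        accepted = set(cazyme_consensus(rows))
        a_only = {(r.gene, r.family) for r in rows
                  if r.a_pident > 40 and r.a_coverage > 0.5}
        b_only = {(r.gene, r.family) for r in rows
                  if r.b_evalue < 1e-15 and r.b_coverage > 0.35}
        assert accepted <= a_only and accepted <= b_only


class TestPulMarkers:
    def test_counts(self):
        rows = ([{"genome": "g1", "gene": f"c{i}", "cazy_family": "GH5",
                  "symbol": None} for i in range(12)]
                + [{"genome": "g1", "gene": f"s{i}", "cazy_family": None,
                    "symbol": "susC"} for i in range(3)]
                + [{"genome": "g1", "gene": f"d{i}", "cazy_family": None,
                    "symbol": "susD"} for i in range(2)])
        out = pul_markers(pd.DataFrame(rows))
        assert out.loc["g1", "cazymes"] == 12
        assert out.loc["g1", "suscd"] == 5

    def test_genome_without_markers(self):
        df = pd.DataFrame([{"genome": "g1", "gene": "x", "cazy_family": None,
                            "symbol": "recA"}])
        out = pul_markers(df)
        assert out.loc["g1", "cazymes"] == 0 and out.loc["g1", "suscd"] == 0

    def test_planted_counts_across_groups(self):
        rng = np.random.default_rng(2)
        rows, expected = [], {}
        for g in range(3):
            genome = f"g{g}"
            n_caz, n_c, n_d = rng.integers(0, 20, size=3)
            expected[genome] = (int(n_caz), int(n_c + n_d))
            rows += [{"genome": genome, "gene": f"{genome}caz{i}",
                      "cazy_family": "GH13", "symbol": None}
                     for i in range(n_caz)]
            rows += [{"genome": genome, "gene": f"{genome}c{i}",
                      "cazy_family": None, "symbol": "susC"}
                     for i in range(n_c)]
            rows += [{"genome": genome, "gene": f"{genome}d{i}",
                      "cazy_family": None, "symbol": "SusD"}
                     for i in range(n_d)]
        out = pul_markers(pd.DataFrame(rows))
        for genome, (caz, suscd) in expected.items():
            assert out.loc[genome, "cazymes"] == caz
            assert out.loc[genome, "suscd"] == suscd


def two_group_values(rng, n=20, shift=0.0):
    values, groups = {}, {}
    for i in range(n):
        values[f"a{i}"] = float(rng.normal(0, 1))
        groups[f"a{i}"] = "A"
        values[f"b{i}"] = float(rng.normal(shift, 1))
        groups[f"b{i}"] = "B"
    return values, groups


class TestCompareGroups:
    def test_group_of_16_is_excluded(self):
        rng = np.random.default_rng(0)
        values, groups = two_group_values(rng, n=20)
        for i in range(16):
            values[f"c{i}"] = float(rng.normal(0, 1))
            groups[f"c{i}"] = "C"
        result = compare_groups(values, groups, min_group_n=17)
        assert result.excluded_groups == ("C",)
        assert result.groups == ("A", "B")

    def test_fewer_than_two_eligible_groups_rejected(self):
        rng = np.random.default_rng(1)
        values, groups = two_group_values(rng, n=10)
        with pytest.raises(ValueError):
            compare_groups(values, groups, min_group_n=17)

    def test_three_iqr_shift_significant_after_correction(self):
        rng = np.random.default_rng(2)
        # IQR of a standard normal is about 1.35; shift by 3 IQR
        values, groups = two_group_values(rng, n=30, shift=3 * 1.35)
        result = compare_groups(values, groups)
        assert ("A", "B") in result.significant_pairs()

    def test_bonferroni_is_raw_times_pair_count_on_three_groups(self):
        rng = np.random.default_rng(3)
        values, groups = {}, {}
        data = {}
        for lab, shift in (("A", 0.0), ("B", 0.4), ("C", 1.0)):
            data[lab] = [float(rng.normal(shift, 1)) for _ in range(20)]
            for i, v in enumerate(data[lab]):
                values[f"{lab}{i}"] = v
                groups[f"{lab}{i}"] = lab
        result = compare_groups(values, groups)
        assert len(result.pairwise) == 3
        for row in result.pairwise.itertuples():
            _, p_raw = stats.mannwhitneyu(data[row.group_a], data[row.group_b],
                                          alternative="two-sided",
                                          method="exact")
            assert row.p_raw == pytest.approx(p_raw)
            assert row.p_corrected == pytest.approx(min(1.0, p_raw * 3))
            assert row.p_corrected >= row.p_raw

    def test_null_rejection_rate_bounded_by_alpha(self):
        rng = np.random.default_rng(4)
        n_sim, rejections = 300, 0
        for _ in range(n_sim):
            values, groups = two_group_values(rng, n=20)
            result = compare_groups(values, groups)
            rejections += bool(result.significant_pairs())
        assert rejections / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)
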