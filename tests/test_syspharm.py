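import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chemscreen.fixtures import FixturePlan, make_expression_fixture, make_network_fixture
from chemscreen.syspharm import (
    build_gene_set,
    enrich,
    merge_dti_sources,
    normalize_symbol,
    overlap_report,
    read_gmt,
    tissue_specific_network,
    tissue_specificity,
    write_gmt,
)


def dti(rows):
    return pd.DataFrame(rows, columns=["drug_id", "gene", "source", "organism"])


class TestDTIMerge:
    def test_same_pair_from_two_sources_merges_keeping_both(self):
        merged = merge_dti_sources([
            dti([("d1", "TP53", "docking", "Homo sapiens")]),
            dti([("d1", "TP53", "literature", "Homo sapiens")]),
        ])
        assert len(merged) == 1
        assert merged.loc[0, "sources"] == "docking;literature"

    def test_non_human_rows_dropped(self):
        merged = merge_dti_sources([
            dti([("d1", "TP53", "docking", "Homo sapiens"),
                 ("d1", "Trp53", "docking", "Mus musculus")]),
        ])
        assert list(merged["gene_symbol"]) == ["TP53"]

    def test_empty_tables_give_empty_network(self):
        assert len(merge_dti_sources([])) == 0
        assert len(merge_dti_sources([dti([])])) == 0

    def test_alias_map_normalizes_symbols(self):
        merged = merge_dti_sources(
            [dti([("d1", "ikba", "docking", "Homo sapiens")])],
            alias_map={"IKBA": "NFKBIA"},
        )
        assert list(merged["gene_symbol"]) == ["NFKBIA"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            merge_dti_sources([pd.DataFrame({"drug_id": ["d"]})])


class TestGeneSet:
    def test_union_of_overlapping_lists(self):
        gs = build_gene_set({"s1": ["A", "B"], "s2": ["B", "C"]})
        assert gs.members == {"A", "B", "C"}
        assert gs.sources == ["s1", "s2"]

    def test_alias_resolution(self):
        gs = build_gene_set({"s": ["IKBA"]}, alias_map={"IKBA": "NFKBIA"})
        assert gs.members == {"NFKBIA"}
        assert normalize_symbol(" tp53 ") == "TP53"

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_gene_set({"s": []})


class TestTissueSpecificity:
    def _expr_from_tissue_means(self, means):
        """One sample per tissue, so per-tissue means are the values."""
        samples = [f"t{i}_s1" for i in range(len(means))]
        labels = pd.Series({s: f"t{i}" for i, s in enumerate(samples)})
        expr = pd.DataFrame([means], index=["g"], columns=samples)
        return expr, labels

    def test_hand_computed_z_for_one_high_tissue(self):
        # per-tissue means {10,4,4,4,4,4}: mean 5, sd sqrt(6) ~ 2.449,
        # z = (10-5)/2.449 ~ 2.04 > 2, all values >= 1 so expressed
        expr, labels = self._expr_from_tissue_means([10, 4, 4, 4, 4, 4])
        res = tissue_specificity(expr, labels, "t0")
        assert res.loc["g", "sd_overall"] == pytest.approx(math.sqrt(6), rel=1e-12)
        assert res.loc["g", "z"] == pytest.approx(5 / math.sqrt(6), rel=1e-12)
        assert bool(res.loc["g", "specific"])

    def test_identical_expression_everywhere_is_non_specific(self):
        expr, labels = self._expr_from_tissue_means([5, 5, 5, 5])
        res = tissue_specificity(expr, labels, "t0")
        assert not bool(res.loc["g", "specific"])
        assert res.loc["g", "reason"] == "sd_zero"
        assert np.isnan(res.loc["g", "z"])

    def test_low_expression_gene_flagged_not_expressed(self):
        expr, labels = self._expr_from_tissue_means([0.5, 0.2, 0.1, 0.3])
        res = tissue_specificity(expr, labels, "t0")
        assert not bool(res.loc["g", "expressed"])
        assert res.loc["g", "reason"] == "not_expressed"

    def test_sample_order_and_tissue_duplication_invariance(self, small_plan):
        fx = make_expression_fixture(small_plan)
        expr = fx["expression"]
        labels = fx["samples"].set_index("sample")["tissue"]
        base = tissue_specificity(expr, labels, "skin")

        perm = np.random.default_rng(0).permutation(expr.columns)
        shuffled = tissue_specificity(expr[perm], labels[perm], "skin")
        pd.testing.assert_frame_equal(base, shuffled)

        # duplicating one tissue's samples leaves per-tissue means unchanged
        dup_cols = [c for c in expr.columns if labels[c] == "tissue2"]
        expr_dup = pd.concat(
            [expr, expr[dup_cols].rename(columns=lambda c: c + "_dup")], axis=1
        )
        labels_dup = pd.concat(
            [labels, pd.Series({c + "_dup": "tissue2" for c in dup_cols})]
        )
        dup = tissue_specificity(expr_dup, labels_dup, "skin")
        pd.testing.assert_series_equal(base["z"], dup["z"])

    def test_planted_specific_genes_recovered_exactly(self, small_plan):
        fx = make_expression_fixture(small_plan)
        gs = tissue_specific_network(
            fx["expression"], fx["samples"].set_index("sample")["tissue"], "skin"
        )
        truth = fx["truth"]
        assert gs.members == set(truth.index[truth["planted_specific"]])

    def test_across_samples_reference_mode(self, small_plan):
        fx = make_expression_fixture(small_plan)
        labels = fx["samples"].set_index("sample")["tissue"]
        res = tissue_specificity(fx["expression"], labels, "skin",
                                 reference="samples")
        # planted genes still clear the cutoff in the across-samples mode
        planted = fx["truth"].index[fx["truth"]["planted_specific"]]
        assert res.loc[planted, "specific"].all()

    def test_errors(self):
        expr, labels = self._expr_from_tissue_means([5, 6])
        with pytest.raises(ValueError, match="tissue"):
            tissue_specificity(expr, labels, "nope")
        with pytest.raises(ValueError, match="non-negative"):
            tissue_specificity(-expr, labels, "t0")
        with pytest.raises(ValueError, match="label"):
            tissue_specificity(expr, labels.iloc[:1], "t0")


class TestOverlap:
    def test_disjoint_sets_give_zero_counts(self):
        rep = overlap_report({"A"}, {"B"}, {"C"})
        c = rep.counts()
        assert c["targets_in_disease"] == c["targets_in_tissue"] == 0
        assert c["targets_in_union"] == 0

    def test_inclusion_exclusion_identity_on_random_sets(self, rng):
        pool = [f"G{i}" for i in range(40)]
        for _ in range(30):
            t = set(rng.choice(pool, 15, replace=False))
            d = set(rng.choice(pool, 10, replace=False))
            s = set(rng.choice(pool, 12, replace=False))
            c = overlap_report(t, d, s).counts()
            assert c["targets_in_union"] == (
                c["targets_in_disease"] + c["targets_in_tissue"]
                - c["targets_in_both"]
            )

    def test_planted_network_fixture_counts(self, small_plan):
        fx = make_network_fixture(small_plan)
        merged = merge_dti_sources(fx["dti_tables"])
        disease = build_gene_set(fx["disease_sources"])
        rep = overlap_report(set(merged["gene_symbol"]), disease,
                             fx["tissue_genes"])
        c = rep.counts()
        for key, want in fx["truth"].items():
            assert c[key] == want, key

    def test_member_lists_sorted_and_within_targets(self):
        rep = overlap_report({"B", "A", "C"}, {"C", "A"}, {"B"})
        assert rep.t_and_d == ["A", "C"]
        assert set(rep.t_and_union) <= rep.targets


class TestEnrichment:
    def test_exact_p_when_hits_equal_term(self):
        universe = [f"G{i}" for i in range(20)]
        term = universe[:5]
        res = enrich(set(term), {"term1": term}, universe, q_max=1.0)
        # P(all 5 draws in the 5-gene term) = 1/C(20,5) = 1/15504
        assert res.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_term_disjoint_from_hits_has_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        res = enrich(set(universe[:3]), {"t": universe[10:15]}, universe, q_max=2.0)
        assert res.loc[0, "p"] == 1.0

    def test_holm_correction_matches_hand_computation(self):
        universe = [f"G{i}" for i in range(20)]
        hits = set(universe[:5])
        ann = {"strong": universe[:5], "weak": universe[4:12]}
        res = enrich(hits, ann, universe, q_max=2.0).set_index("term")
        # Holm on sorted p: q1 = 2*p1, q2 = max(q1, 1*p2)
        p1, p2 = sorted(res["p"])
        assert res["q"].min() == pytest.approx(min(2 * p1, 1.0))
        assert res["q"].max() == pytest.approx(max(2 * p1, p2))

    def test_hypergeometric_matches_exhaustive_enumeration(self, rng):
        # brute-force oracle: enumerate every possible hit draw
        for n_universe, n_term, n_hits in [(10, 4, 3), (12, 5, 4), (25, 6, 5)]:
            universe = [f"G{i}" for i in range(n_universe)]
            term = set(rng.choice(universe, n_term, replace=False))
            hits = set(rng.choice(universe, n_hits, replace=False))
            k = len(hits & term)
            total = hit_count = 0
            for draw in itertools.combinations(universe, n_hits):
                total += 1
                if len(set(draw) & term) >= k:
                    hit_count += 1
            res = enrich(hits, {"t": sorted(term)}, universe, q_max=2.0)
            assert res.loc[0, "p"] == pytest.approx(hit_count / total, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="universe"):
            enrich({"A"}, {}, set())
        with pytest.raises(ValueError, match="outside"):
            enrich({"A"}, {}, {"B"})


class TestGMT:
    def test_roundtrip(self, tmp_path):
        terms = {"t1": ["A", "B"], "t2": ["B", "C", "D"]}
        p = tmp_path / "ann.gmt"
        write_gmt(terms, p)
        back = read_gmt(p)
        assert {k: sorted(v) for k, v in back.items()} == \
               {k: sorted(v) for k, v in terms.items()}

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("term_only\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(p)
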