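import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batmuscle import (
    AnnotationMap,
    cluster_modules,
    contrast_overlap,
    filter_degs,
    gene_term_profiles,
    jaccard,
    merge_annotations,
    module_venn,
    ora,
    read_gmt,
    write_gmt,
)


def deg_df(rows):
    return pd.DataFrame(rows, columns=["gene", "contrast", "log2fc", "p", "q"])


TOY_DEGS = deg_df([
    ("g1", "c", 2.0, 1e-4, 0.001),
    ("g2", "c", 1.2, 1e-4, 0.001),
    ("g3", "c", 1.8, 0.1, 0.2),
    ("g4", "c", -1.7, 1e-3, 0.004),
    ("g5", "c", 0.5, 0.3, 0.5),
])


class TestFilterDegs:
    def test_hand_enumerated_survivors(self):
        out, summary = filter_degs(TOY_DEGS, 1.5, 0.01)
        assert sorted(out["gene"]) == ["g1", "g4"]
        assert dict(zip(out["gene"], out["direction"])) == {"g1": "up", "g4": "down"}
        assert summary.loc[0, "up"] == 1 and summary.loc[0, "down"] == 1

    def test_empty_table(self):
        out, summary = filter_degs(deg_df([]), 1.0, 0.05)
        assert len(out) == 0 and len(summary) == 0

    def test_vacuous_thresholds_keep_nonzero_fc(self):
        out, _ = filter_degs(TOY_DEGS, 1e-12, 1.0)
        assert sorted(out["gene"]) == ["g1", "g2", "g3", "g4", "g5"]

    def test_survivors_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        table = deg_df([(f"g{i}", "c", rng.normal(0, 2), 0.01, rng.uniform())
                        for i in range(200)])
        sizes_fc = [len(filter_degs(table, fc, 0.5)[0]) for fc in (0.5, 1.0, 2.0)]
        assert sizes_fc == sorted(sizes_fc, reverse=True)
        sizes_q = [len(filter_degs(table, 0.5, q)[0]) for q in (0.5, 0.1, 0.01)]
        assert sizes_q == sorted(sizes_q, reverse=True)

    def test_strict_inequalities(self):
        table = deg_df([("a", "c", 1.5, 0.001, 0.001), ("b", "c", 1.6, 0.01, 0.01)])
        out, _ = filter_degs(table, 1.5, 0.01)
        assert len(out) == 0  # 1.5 is not > 1.5; 0.01 is not < 0.01


class TestContrastOverlap:
    def test_identity_and_simple_partition(self):
        same = contrast_overlap({"x", "y"}, {"x", "y"})
        assert same["only_a"] == set() and same["both"] == {"x", "y"}
        v = contrast_overlap({"x", "y"}, {"y", "z"})
        assert (v["only_a"], v["both"], v["only_b"]) == ({"x"}, {"y"}, {"z"})

    def test_partition_conserves_union_on_random_sets(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(150)]
        a = {g for g in genes if rng.random() < 0.4}
        b = {g for g in genes if rng.random() < 0.4}
        v = contrast_overlap(a, b)
        # brute-force membership scan
        for g in genes:
            regions = [g in v["only_a"], g in v["both"], g in v["only_b"]]
            assert sum(regions) == (1 if g in a | b else 0)
        assert sum(v["counts"].values()) == len(a | b)


def ora_exact_tail(N, K, n, k):
    """Independent hypergeometric upper tail from binomial coefficients."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def annotation(universe, term_sets):
    return AnnotationMap(
        terms={tid: (tid, frozenset(genes)) for tid, genes in term_sets.items()},
        universe=frozenset(universe))


class TestOra:
    def test_term_equal_to_universe_certain(self):
        uni = [f"g{i}" for i in range(8)]
        ann = annotation(uni, {"all": uni})
        res = ora(set(uni[:3]), ann)
        assert res.loc[0, "k"] == 3
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_combinatorial_hand_example(self):
        uni = [f"g{i}" for i in range(10)]
        ann = annotation(uni, {"t": uni[:5]})
        res = ora(set(uni[:4]), ann)  # k=4, K=5, n=4, N=10
        assert res.loc[0, "p"] == pytest.approx(5 / 210)

    def test_matches_exhaustive_draw_enumeration(self):
        # tiny instance: enumerate every C(N, n) study draw literally
        N, K, n = 12, 5, 4
        uni = list(range(N))
        term = set(uni[:K])
        ann = annotation([str(g) for g in uni], {"t": [str(g) for g in term]})
        for k_obs in range(0, n + 1):
            study = set(str(g) for g in uni[:k_obs]) | set(
                str(g) for g in uni[K:K + n - k_obs])
            res = ora(study, ann)
            count = sum(1 for draw in itertools.combinations(uni, n)
                        if len(set(draw) & term) >= k_obs)
            assert res.loc[0, "p"] == pytest.approx(count / math.comb(N, n))

    def test_matches_binomial_formula_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            uni = [f"g{i}" for i in range(N)]
            term = rng.choice(uni, size=K, replace=False).tolist()
            study = set(rng.choice(uni, size=n, replace=False).tolist())
            ann = annotation(uni, {"t": term})
            res = ora(study, ann)
            k = len(study & set(term))
            assert res.loc[0, "p"] == pytest.approx(
                ora_exact_tail(N, K, n, k), rel=1e-10)

    def test_study_outside_universe_rejected(self):
        ann = annotation(["a", "b"], {"t": ["a"]})
        with pytest.raises(ValueError, match="stranger"):
            ora({"a", "stranger"}, ann)

    def test_term_size_window(self):
        uni = [f"g{i}" for i in range(10)]
        ann = annotation(uni, {"small": uni[:1], "mid": uni[:4], "big": uni[:9]})
        res = ora(set(uni[:2]), ann, min_term_size=2, max_term_size=5)
        assert list(res["term_id"]) == ["mid"]


class TestProfilesAndJaccard:
    def test_incidence_fixture_profiles(self):
        terms = {"A": ["g1", "g2"], "B": ["g2", "g3"], "C": ["g4"], "D": []}
        terms.pop("D")
        ann = annotation(["g1", "g2", "g3", "g4", "g5", "g6"], terms)
        profiles, lost = gene_term_profiles(
            ["g1", "g2", "g3", "g4", "g5", "g6"], ann)
        assert profiles == {"g1": {"A"}, "g2": {"A", "B"}, "g3": {"B"},
                            "g4": {"C"}}
        assert lost == ["g5", "g6"]

    def test_profiles_from_enrichment_respect_q_cut(self):
        ann = annotation(["g1", "g2"], {"A": ["g1"], "B": ["g2"]})
        enriched = pd.DataFrame({"term_id": ["A", "B"], "q": [0.001, 0.9]})
        profiles, lost = gene_term_profiles(["g1", "g2"], enriched, ann=ann,
                                            max_term_q=0.05)
        assert profiles == {"g1": {"A"}} and lost == ["g2"]

    @pytest.mark.parametrize("a,b,expected", [
        ({"A", "B", "C"}, {"A", "B", "C"}, 1.0),
        ({"A"}, {"B"}, 0.0),
        ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
    ])
    def test_jaccard_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_jaccard_undefined_for_two_empty_sets(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 12)), st.sets(st.integers(0, 12)))
    def test_jaccard_properties(self, a, b):
        if not (a or b):
            return
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        assert (j == 1.0) == (a == b)
        assert (j == 0.0) == (not a & b)


class TestClusterModules:
    def test_k1_single_module_no_secondaries(self):
        profiles = {"a": {"T1"}, "b": {"T2"}, "c": {"T3"}}
        out = cluster_modules(profiles, k=1)
        assert set(out["primary_module"]) == {1}
        assert all(s == [] for s in out["secondary_modules"])

    def test_two_perfect_blocks_recovered(self):
        profiles = {"a": {"T1", "T2"}, "b": {"T1", "T2"},
                    "c": {"T3", "T4"}, "d": {"T3", "T4"}}
        out = cluster_modules(profiles, k=2).set_index("gene")
        assert out.loc["a", "primary_module"] == out.loc["b", "primary_module"]
        assert out.loc["c", "primary_module"] == out.loc["d", "primary_module"]
        assert out.loc["a", "primary_module"] != out.loc["c", "primary_module"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        terms = [f"T{i}" for i in range(12)]
        profiles = {f"g{i:02d}": set(rng.choice(terms, size=4, replace=False))
                    for i in range(15)}
        out1 = cluster_modules(profiles, k=3)
        shuffled = dict(reversed(list(profiles.items())))
        out2 = cluster_modules(shuffled, k=3)
        pd.testing.assert_frame_equal(out1, out2)

    def test_secondary_membership_by_term_union_jaccard(self):
        profiles = {"a": {"T1", "T2"}, "b": {"T1", "T2"},
                    "c": {"T3", "T4"}, "d": {"T3", "T4", "T1", "T2"}}
        out = cluster_modules(profiles, k=2, secondary_threshold=0.5).set_index("gene")
        # d straddles both blocks: primary in one, secondary in the other
        membership = {out.loc["d", "primary_module"], *out.loc["d", "secondary_modules"]}
        assert membership == {1, 2}
        assert out.loc["a", "secondary_modules"] == []

    def test_errors_on_empty_profiles_or_too_few_genes(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_modules({"a": set(), "b": {"T"}}, k=1)
        with pytest.raises(ValueError, match="need >="):
            cluster_modules({"a": {"T"}}, k=2)


class TestModuleVenn:
    @staticmethod
    def assignments(rows):
        return pd.DataFrame(rows, columns=["gene", "primary_module",
                                           "secondary_modules"])

    def test_pure_partition(self):
        a = self.assignments([("a", 1, []), ("b", 1, []), ("c", 2, [])])
        regions = module_venn(a)
        assert regions == {frozenset({1}): 2, frozenset({2}): 1}

    def test_single_shared_gene(self):
        a = self.assignments([("a", 1, [2]), ("b", 1, []), ("c", 2, [])])
        regions = module_venn(a)
        assert regions[frozenset({1, 2})] == 1

    def test_random_fixture_matches_scan(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(60):
            primary = int(rng.integers(1, 4))
            secondary = [m for m in (1, 2, 3)
                         if m != primary and rng.random() < 0.2]
            rows.append((f"g{i}", primary, secondary))
        a = self.assignments(rows)
        regions = module_venn(a, modules=(1, 2, 3))
        # brute-force per-gene region classification
        expected: dict = {}
        for g, primary, secondary in rows:
            key = frozenset({primary} | set(secondary))
            expected[key] = expected.get(key, 0) + 1
        assert regions == expected
        assert sum(regions.values()) == len(rows)  # cardinality conserved


class TestGmtIo:
    def test_round_trip_and_prefixing(self, tmp_path):
        ann = annotation(["g1", "g2", "g3"], {"t1": ["g1", "g2"], "t2": ["g3"]})
        path = tmp_path / "a.gmt"
        write_gmt(ann, path)
        back = read_gmt(path)
        assert {tid: genes for tid, (_, genes) in back.terms.items()} == {
            "t1": frozenset({"g1", "g2"}), "t2": frozenset({"g3"})}
        prefixed = read_gmt(path, source_prefix="kegg")
        assert set(prefixed.terms) == {"kegg:t1", "kegg:t2"}

    def test_merge_prefixes_sources(self):
        a = annotation(["g1"], {"t": ["g1"]})
        b = annotation(["g2"], {"t": ["g2"]})
        merged = merge_annotations({"kegg": a, "reactome": b})
        assert set(merged.terms) == {"kegg:t", "reactome:t"}
        assert merged.universe == frozenset({"g1", "g2"})

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotation(["g1"], {"t": []})

    def test_annotated_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AnnotationMap(terms={"t": ("t", frozenset({"zz"}))},
                          universe=frozenset({"g1"}))
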