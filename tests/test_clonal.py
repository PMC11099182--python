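"""Clonal-family partitioning, diversity statistics and the overlap test."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from clonsig.clonal import (
    ClonalFamilyClusterer,
    ClonalPartition,
    cdr3_identity,
    cluster_simpson,
    family_diversity,
    overlap_table,
    partition_families,
    permutation_overlap_test,
    simpson_index,
)

from conftest import make_pair, mutate


def exact_pair_distance(pa, pb):
    """Exact rational per-chain Hamming distance (max over chains)."""
    dh = Fraction(
        sum(x != y for x, y in zip(pa.heavy.cdr3_nt, pb.heavy.cdr3_nt)),
        len(pa.heavy.cdr3_nt),
    )
    dl = Fraction(
        sum(x != y for x, y in zip(pa.light.cdr3_nt, pb.light.cdr3_nt)),
        len(pa.light.cdr3_nt),
    )
    return max(dh, dl)


def oracle_complete_linkage(cells, distance, dmax):
    """Exhaustive complete-linkage reference: recompute every cluster-pair
    distance from the raw pairwise function at each step, merge the closest
    pair (ties by smallest member ids) while strictly below dmax.  Run with
    Fraction-valued distances and dmax for exact boundary semantics."""
    clusters = [frozenset([c]) for c in cells]
    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(clusters, 2):
            d = max(distance(x, y) for x in a for y in b)
            candidates.append((d, min(a), min(b), a, b) if min(a) < min(b)
                              else (d, min(b), min(a), b, a))
        candidates.sort(key=lambda t: t[:3])
        d, _, _, a, b = candidates[0]
        if not d < dmax:
            break
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return {frozenset(c) for c in clusters}


def partition_sets(partition: ClonalPartition):
    return {frozenset(m) for m in partition.members.values()}


class TestCdr3Identity:
    def test_identical(self):
        assert cdr3_identity("ACGTACGTACGTACG", "ACGTACGTACGTACG") == 1.0

    def test_boundary_three_of_fifteen(self):
        a = "ACGTACGTACGTACG"
        b = "TCGTTCGTACGTACT"  # 3 mismatches
        assert cdr3_identity(a, b) == pytest.approx(0.8, abs=0)

    def test_two_of_fifteen(self):
        a = "ACGTACGTACGTACG"
        b = "TCGTACGTACGTACT"
        assert cdr3_identity(a, b) == pytest.approx(13 / 15)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            cdr3_identity("ACGT", "ACGTA")


class TestPartitionFamilies:
    def test_all_pairs_close_one_family(self):
        base_h = "ACGTACGTACGTACG"
        base_l = "TTTACGTACGTA"
        rng = np.random.default_rng(0)
        pairs = [
            make_pair("C1", base_h, base_l),
            make_pair("C2", mutate(base_h, [0], rng), base_l),
            make_pair("C3", base_h, mutate(base_l, [1], rng)),
        ]
        part = partition_families(pairs)
        assert len(part.members) == 1

    def test_boundary_identity_not_coclustered(self):
        a = "ACGTACGTACGTACG"
        b = "TCGTTCGTACGTACT"  # identity exactly 0.8 on the heavy chain
        pairs = [make_pair("C1", a, "TTTACGTACGTA"), make_pair("C2", b, "TTTACGTACGTA")]
        part = partition_families(pairs)
        assert part.family_of_cell["C1"] != part.family_of_cell["C2"]

    def test_chain_ambiguity_resolved_by_oracle(self):
        # identities a-b 0.87, b-c 0.87, a-c 0.73 on the heavy chain
        a = "ACGTACGTACGTACG"
        b = "TCGTTCGTACGTACG"  # 2 from a
        c = "TCGTTCGTTCGTTCG"  # 2 from b, 4 from a
        light = "TTTACGTACGTA"
        pairs = {n: make_pair(n, h, light) for n, h in zip("abc", (a, b, c))}
        part = partition_families(list(pairs.values()))

        def dist(x, y):
            return exact_pair_distance(pairs[x], pairs[y])

        expected = oracle_complete_linkage(list("abc"), dist, Fraction(1, 5))
        assert partition_sets(part) == expected

    def test_key_mismatch_separates(self):
        p1 = make_pair("C1", vh="VH1")
        p2 = make_pair("C2", vh="VH2")
        part = partition_families([p1, p2])
        assert len(part.members) == 2

    def test_light_v_gene_mismatch_separates(self):
        p1 = make_pair("C1", vl="VL1")
        p2 = make_pair("C2", vl="VL2")
        assert len(partition_families([p1, p2]).members) == 2

    def test_missing_donor_errors(self):
        p = make_pair("C1")
        p.donor = ""
        with pytest.raises(ValueError, match="donor"):
            partition_families([p])

    def test_families_never_span_donors(self):
        p1 = make_pair("C1", donor="D1")
        p2 = make_pair("C2", donor="D2")
        assert len(partition_families([p1, p2]).members) == 2

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        base_h, base_l = "ACGTACGTACGTACG", "TTTACGTACGTA"
        pairs = [
            make_pair(f"C{i}", mutate(base_h, rng.choice(15, rng.integers(0, 4), replace=False), rng), base_l)
            for i in range(8)
        ]
        ref = partition_sets(partition_families(pairs))
        for _ in range(5):
            rng.shuffle(pairs)
            assert partition_sets(partition_families(pairs)) == ref

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        base_h, base_l = "ACGTACGTACGTACG", "TTTACGTACGTA"
        pairs = [
            make_pair(f"C{i}", mutate(base_h, rng.choice(15, rng.integers(0, 5), replace=False), rng),
                      mutate(base_l, rng.choice(12, rng.integers(0, 3), replace=False), rng))
            for i in range(12)
        ]
        sizes = [
            len(partition_families(pairs, identity_threshold=t).members)
            for t in (0.6, 0.7, 0.8, 0.9, 0.95)
        ]
        assert sizes == sorted(sizes)

    def test_oracle_equivalence_random_groups(self):
        """Complete-linkage agreement with the exhaustive reference on
        random same-key groups (the acceptance run uses 500 groups)."""
        rng = np.random.default_rng(5)
        for trial in range(100):
            n = int(rng.integers(2, 9))
            lh = int(rng.integers(4, 7)) * 3
            ll = int(rng.integers(3, 5)) * 3
            base_h = "".join(rng.choice(list("AC"), lh))
            base_l = "".join(rng.choice(list("AC"), ll))
            pairs = {}
            for i in range(n):
                h = mutate(base_h, rng.choice(lh, rng.integers(0, lh // 2), replace=False), rng)
                light = mutate(base_l, rng.choice(ll, rng.integers(0, ll // 3), replace=False), rng)
                pairs[f"C{i}"] = make_pair(f"C{i}", h, light)
            part = partition_families(list(pairs.values()))

            def dist(x, y):
                return exact_pair_distance(pairs[x], pairs[y])

            expected = oracle_complete_linkage(sorted(pairs), dist, Fraction(1, 5))
            assert partition_sets(part) == expected, f"trial {trial}"

    def test_germline_key_splits_distinct_germlines(self):
        p1 = make_pair("C1")
        p2 = make_pair("C2")
        p2.germline_fr_heavy = p2.germline_fr_heavy[:-1] + (
            "A" if p2.germline_fr_heavy[-1] != "A" else "C"
        )
        assert len(partition_families([p1, p2], use_germline_key=True).members) == 2
        assert len(partition_families([p1, p2], use_germline_key=False).members) == 1

    def test_sklearn_params_roundtrip(self):
        est = ClonalFamilyClusterer(identity_threshold=0.9, chain_mode="joint")
        clone = ClonalFamilyClusterer(**est.get_params())
        assert clone.get_params() == est.get_params()


def toy_partition(fams):
    part = ClonalPartition({c: f for c, f in fams.items()})
    members = {}
    for c, f in fams.items():
        members.setdefault(f, []).append(c)
    part.members = {f: sorted(m) for f, m in members.items()}
    return part


class TestDiversityStats:
    def test_family_diversity_singletons(self):
        part = toy_partition({f"C{i}": f"F{i}" for i in range(5)})
        counts = family_diversity(part, {f"C{i}": "k1" for i in range(5)})
        assert counts["k1"] == 5

    def test_family_spanning_clusters_counted_in_each(self):
        part = toy_partition({"C1": "F1", "C2": "F1"})
        counts = family_diversity(part, {"C1": "k1", "C2": "k2"})
        assert counts["k1"] == 1 and counts["k2"] == 1

    def test_diversity_matches_truth(self, small_repertoire):
        from clonsig.io import pairs_from_table

        table, truth = small_repertoire
        pairs, _ = pairs_from_table(table)
        part = partition_families(pairs.values())
        counts = family_diversity(part, {c: "all" for c in pairs})
        expected = len({truth.family_of_cell[c] for c in pairs})
        assert counts["all"] == expected

    def test_simpson_closed_forms(self):
        assert simpson_index(["F1"] * 7) == 0.0
        assert simpson_index(["F1", "F1", "F2", "F2"]) == pytest.approx(0.5)
        n = 11
        assert simpson_index([f"F{i}" for i in range(n)]) == pytest.approx(1 - 1 / n)
        assert simpson_index([f"F{i}" for i in range(n)], unbiased=True) == pytest.approx(1.0)

    def test_simpson_empty_cluster_errors(self):
        with pytest.raises(ValueError, match="empty"):
            simpson_index([])

    def test_simpson_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 5, rng.integers(1, 30))
            assert 0.0 <= simpson_index(labels) <= 1.0

    def test_cluster_simpson(self):
        part = toy_partition({"C1": "F1", "C2": "F1", "C3": "F2", "C4": "F2"})
        s = cluster_simpson(part, {"C1": "k1", "C2": "k1", "C3": "k1", "C4": "k1"})
        assert s["k1"] == pytest.approx(0.5)


class TestOverlap:
    def test_disjoint_families_zero_offdiagonal(self):
        part = toy_partition({"C1": "F1", "C2": "F2"})
        tab = overlap_table(part, {"C1": "k1", "C2": "k2"})
        assert tab.loc["k1", "k2"] == 0
        assert tab.loc["k1", "k1"] == 1

    def test_spanning_family_counts_once(self):
        part = toy_partition({"C1": "F1", "C2": "F1", "C3": "F2"})
        tab = overlap_table(part, {"C1": "k1", "C2": "k4", "C3": "k1"})
        assert tab.loc["k1", "k4"] == 1
        assert tab.equals(tab.T)

    def test_against_set_intersection_oracle(self):
        rng = np.random.default_rng(6)
        cells = [f"C{i}" for i in range(80)]
        fams = {c: f"F{rng.integers(0, 12)}" for c in cells}
        clus = {c: f"k{rng.integers(0, 5)}" for c in cells}
        tab = overlap_table(toy_partition(fams), clus)
        for ka, kb in itertools.product(sorted(set(clus.values())), repeat=2):
            fa = {fams[c] for c in cells if clus[c] == ka}
            fb = {fams[c] for c in cells if clus[c] == kb}
            assert tab.loc[ka, kb] == len(fa & fb)

    def test_permutation_floor_at_maximal_overlap(self):
        # every family spans both clusters (theoretical maximum overlap);
        # random relabellings essentially never reproduce it, so the
        # add-one estimator sits at its floor 1/(n_perm+1)
        fams = {f"C{i:02d}": f"F{i % 20:02d}" for i in range(40)}
        grouping = {c: ("k1" if int(c[1:]) < 20 else "k2") for c in fams}
        p = permutation_overlap_test(toy_partition(fams), grouping, n_perm=99, seed=0)
        assert p.loc["k1", "k2"] == pytest.approx(1 / 100)

    def test_permutation_pvalues_seeded(self):
        rng = np.random.default_rng(7)
        cells = [f"C{i}" for i in range(40)]
        fams = {c: f"F{rng.integers(0, 8)}" for c in cells}
        clus = {c: f"k{rng.integers(0, 3)}" for c in cells}
        part = toy_partition(fams)
        p1 = permutation_overlap_test(part, clus, n_perm=100, seed=5)
        p2 = permutation_overlap_test(part, clus, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_calibration_under_null(self):
        """Type-I error at alpha=0.05 near nominal (small-scale version of
        the 500-dataset calibration)."""
        rng = np.random.default_rng(8)
        rejections = []
        for d in range(60):
            n = 200
            fams = {f"C{i}": f"F{rng.integers(0, 50):02d}" for i in range(n)}
            clus = {f"C{i}": f"k{rng.integers(0, 4)}" for i in range(n)}
            p = permutation_overlap_test(toy_partition(fams), clus, n_perm=200, seed=d)
            ks = sorted(set(clus.values()))
            vals = [p.loc[a, b] for i, a in enumerate(ks) for b in ks[i + 1:]]
            rejections.append(np.mean([v <= 0.05 for v in vals]))
        assert 0.01 <= np.mean(rejections) <= 0.09
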