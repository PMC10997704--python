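"""Bray-Curtis matrices, Ward.D clustering, cophenetic distances, Mantel test
and tanglegram entanglement."""

import itertools

import numpy as np
import pytest

from dermocybe.congruence import (
    AlignedSequenceSet,
    Dendrogram,
    DistanceMatrix,
    alignment_distance,
    bray_curtis_matrix,
    cophenetic,
    entanglement,
    entanglement_from_orders,
    mantel,
    tanglegram_report,
    ward_cluster,
)
from dermocybe.simulate import EvolSimParams, simulate_coupled_dataset
from tests.conftest import random_distance_matrix


def brute_force_ward(labels, values):
    """Naive O(n^3) Ward.D agglomerator used as an independent oracle.

    Keeps explicit frozensets of leaves, recomputes the full pair scan at
    every step and applies the Lance-Williams Ward update, breaking ties on
    the smallest original leaf indices.
    """
    clusters = {frozenset([i]): None for i in range(len(labels))}
    dist = {
        frozenset([frozenset([i]), frozenset([j])]): values[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    merges = []
    ids = {frozenset([i]): i for i in range(len(labels))}
    next_id = len(labels)
    while len(clusters) > 1:
        items = sorted(clusters, key=lambda c: min(c))
        best = None
        for a, b in itertools.combinations(items, 2):
            d = dist[frozenset([a, b])]
            key = (d, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        h = dist[frozenset([a, b])]
        new = a | b
        for c in list(clusters):
            if c in (a, b):
                continue
            na, nb, nc = len(a), len(b), len(c)
            d_new = (
                (na + nc) * dist[frozenset([a, c])]
                + (nb + nc) * dist[frozenset([b, c])]
                - nc * h
            ) / (na + nb + nc)
            dist[frozenset([new, c])] = d_new
        del clusters[a], clusters[b]
        clusters[new] = None
        merges.append((ids[a], ids[b], h))
        ids[new] = next_id
        next_id += 1
    return merges


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis_matrix(np.array([[1.0, 2, 3], [1, 2, 3]]), ["a", "b"])
        assert d.values[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = bray_curtis_matrix(np.array([[1.0, 0], [0, 2]]), ["a", "b"])
        assert d.values[0, 1] == 1.0

    def test_hand_value(self):
        d = bray_curtis_matrix(np.array([[10.0, 0, 5], [5, 5, 5]]), ["a", "b"])
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_matrix(np.array([[1.0, -1], [1, 1]]), ["a", "b"])

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis_matrix(np.array([[0.0, 0], [1, 1]]), ["a", "b"])

    def test_output_invariants(self, rng):
        x = rng.random((6, 10))
        d = bray_curtis_matrix(x, [f"t{i}" for i in range(6)])
        assert (d.values <= 1 + 1e-12).all()
        assert (d.values >= 0).all()
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0)


class TestAlignmentDistance:
    def test_identical_sequences_zero(self):
        a = AlignedSequenceSet(["x", "y"], ["ACGT", "ACGT"])
        assert alignment_distance(a).values[0, 1] == 0.0

    def test_fully_different_sequences_one(self):
        a = AlignedSequenceSet(["x", "y"], ["AAAA", "CCCC"])
        assert alignment_distance(a).values[0, 1] == 1.0

    def test_gap_counts_as_fifth_state(self):
        a = AlignedSequenceSet(["x", "y"], ["AC-T", "ACGT"])
        assert alignment_distance(a).values[0, 1] == pytest.approx(0.25)

    def test_equals_p_distance_on_n_free_alignments(self, rng):
        alphabet = np.array(list("ACGT-"))
        for _ in range(200):
            n, L = int(rng.integers(2, 6)), int(rng.integers(4, 40))
            seqs = ["".join(rng.choice(alphabet, L)) for _ in range(n)]
            a = AlignedSequenceSet([f"s{i}" for i in range(n)], seqs)
            d = alignment_distance(a).values
            for i in range(n):
                for j in range(i + 1, n):
                    p_dist = np.mean(
                        [x != y for x, y in zip(seqs[i], seqs[j])]
                    )
                    assert d[i, j] == pytest.approx(p_dist, abs=1e-12)

    def test_n_columns_excluded_pairwise(self):
        a = AlignedSequenceSet(["x", "y"], ["ANCT", "AGGT"])
        # column 2 (N) excluded: 3 comparable columns, 1 mismatch
        assert alignment_distance(a).values[0, 1] == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AlignedSequenceSet(["x", "y"], ["ACGT", "ACG"])


class TestWardClustering:
    def test_three_taxon_lance_williams_hand_example(self):
        m = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], float)
        t = ward_cluster(DistanceMatrix(["A", "B", "C"], m))
        assert t.merges[0][:2] == (0, 1) and t.merges[0][2] == 1.0
        assert t.merges[1][2] == pytest.approx(19 / 3)

    def test_two_taxa_single_merge(self):
        m = np.array([[0, 2.5], [2.5, 0]])
        t = ward_cluster(DistanceMatrix(["A", "B"], m))
        assert t.merges == [(0, 1, 2.5)]

    def test_matches_hclust_ward_d_on_frozen_matrix(self):
        # reference merge heights and topology computed with R hclust(..., "ward.D")
        vals = {(0, 1): 2, (0, 2): 5, (0, 3): 9, (0, 4): 7, (0, 5): 4,
                (1, 2): 3, (1, 3): 8, (1, 4): 6, (1, 5): 5.5,
                (2, 3): 7.5, (2, 4): 2.5, (2, 5): 6.5,
                (3, 4): 4.5, (3, 5): 8.5, (4, 5): 3.5}
        m = np.zeros((6, 6))
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        t = ward_cluster(DistanceMatrix(list("ABCDEF"), m))
        assert t.heights() == pytest.approx([2.0, 2.5, 17 / 3, 43 / 6, 61 / 6])
        coph = t.cophenetic().values
        lab = t.cophenetic().labels
        d = lambda a, b: coph[lab.index(a), lab.index(b)]
        assert d("A", "B") == pytest.approx(2.0)
        assert d("C", "E") == pytest.approx(2.5)
        assert d("A", "F") == pytest.approx(17 / 3)  # F joins (A,B)
        assert d("C", "D") == pytest.approx(43 / 6)  # D joins (C,E)
        assert d("A", "C") == pytest.approx(61 / 6)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_oracle(self, n, rng):
        for _ in range(20):
            d = random_distance_matrix(rng, n)
            t = ward_cluster(d)
            oracle = brute_force_ward(d.labels, d.values)
            assert len(t.merges) == len(oracle)
            for (a, b, h), (oa, ob, oh) in zip(t.merges, oracle):
                assert {a, b} == {oa, ob}
                assert h == pytest.approx(oh)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))

    def test_ward_d2_variant(self, rng):
        d = random_distance_matrix(rng, 5)
        t = ward_cluster(d, variant="ward.D2")
        # first merge height equals the smallest dissimilarity in both variants
        assert t.merges[0][2] == pytest.approx(d.values[np.nonzero(d.values)].min())


class TestCophenetic:
    def test_two_leaf_tree(self):
        t = Dendrogram(["A", "B"], [(0, 1, 1.5)])
        assert cophenetic(t).values[0, 1] == 1.5

    def test_chain_tree_lca_height(self):
        t = Dendrogram(["A", "B", "C"], [(0, 1, 1.0), (3, 2, 4.0)])
        c = cophenetic(t).values
        assert c[0, 1] == 1.0 and c[0, 2] == 4.0 and c[1, 2] == 4.0

    def test_matches_brute_force_lca(self, rng):
        for _ in range(20):
            d = random_distance_matrix(rng, 6)
            t = ward_cluster(d)
            sets = t.leaf_sets()
            coph = cophenetic(t).values
            for i in range(6):
                for j in range(i + 1, 6):
                    # brute-force: smallest-height node containing both leaves
                    h = min(
                        h
                        for k, (_, _, h) in enumerate(t.merges)
                        if {i, j} <= sets[6 + k]
                    )
                    assert coph[i, j] == pytest.approx(h)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        d = random_distance_matrix(rng, 7)
        res = mantel(d, d, permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        d = random_distance_matrix(rng, 7)
        d2 = DistanceMatrix(d.labels, 3.0 * d.values + 0.0)
        assert mantel(d, d2, permutations=99, seed=0).r == pytest.approx(1.0)

    def test_p_resolution(self, rng):
        d1, d2 = random_distance_matrix(rng, 8), random_distance_matrix(rng, 8)
        res = mantel(d1, d2, permutations=999, seed=4)
        assert (res.p * 1000) == pytest.approx(round(res.p * 1000))
        assert 0 < res.p <= 1

    def test_labels_aligned_by_name(self, rng):
        d1 = random_distance_matrix(rng, 6)
        perm = list(reversed(range(6)))
        d2 = DistanceMatrix(
            [d1.labels[i] for i in perm], d1.values[np.ix_(perm, perm)]
        )
        assert mantel(d1, d2, permutations=99, seed=0).r == pytest.approx(1.0)

    def test_label_mismatch_rejected(self, rng):
        d1 = random_distance_matrix(rng, 5)
        d2 = random_distance_matrix(rng, 5, labels=[f"u{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel(d1, d2)

    def test_constant_triangle_rejected(self):
        ones = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(list("ABCD"), ones)
        with pytest.raises(ValueError, match="constant"):
            mantel(d, d)

    def test_r_agrees_with_skbio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1 = random_distance_matrix(rng, 9)
        d2 = random_distance_matrix(rng, 9)
        ours = mantel(d1, d2, permutations=0, seed=0)
        theirs_r, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, d1.labels),
            skbio_distance.DistanceMatrix(d2.values, d2.labels),
            method="pearson",
            permutations=0,
        )
        assert ours.r == pytest.approx(theirs_r, abs=1e-10)


class TestEntanglement:
    def test_identical_dendrograms_zero(self, rng):
        d = random_distance_matrix(rng, 6)
        t = ward_cluster(d)
        assert entanglement(t, t) == 0.0

    def test_exact_reversal_is_one(self):
        assert entanglement_from_orders(list("ABCD"), list("DCBA")) == 1.0

    def test_adjacent_transposition_hand_value(self):
        assert entanglement_from_orders(
            ["1", "2", "3", "4"], ["1", "3", "2", "4"]
        ) == pytest.approx(0.1)

    def test_leaf_set_mismatch_rejected(self, rng):
        t1 = ward_cluster(random_distance_matrix(rng, 4))
        t2 = ward_cluster(random_distance_matrix(rng, 4, labels=list("wxyz")))
        with pytest.raises(ValueError):
            entanglement(t1, t2)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            t1 = ward_cluster(random_distance_matrix(rng, 7))
            t2 = ward_cluster(random_distance_matrix(rng, 7))
            assert 0.0 <= entanglement(t1, t2) <= 1.0


class TestTanglegram:
    FIG3_ABBREVIATIONS = [
        "C.cin", "C.fer", "C.had", "C.hol", "C.hur", "C.mal",
        "C.omi", "C.pel", "C.pur", "C.rub", "C.san", "C.vit",
    ]

    def test_positive_control_coupled_data(self):
        params = EvolSimParams(
            group_structure=[[f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)]],
            pigment_noise=0.0,
            seed=7,
        )
        alignment, prof = simulate_coupled_dataset(params)
        report = tanglegram_report(prof, alignment, permutations=999, seed=7)
        assert report.mantel.r > 0
        assert report.mantel.p <= 0.05

    def test_identical_inputs_give_perfect_congruence(self, rng):
        # both sides derived from the same abundance table
        x = rng.random((6, 15)) + 0.1
        labels = [f"t{i}" for i in range(6)]
        d = bray_curtis_matrix(x, labels)
        t = ward_cluster(d)
        assert entanglement(t, t) == 0.0
        assert mantel(d, d, permutations=99, seed=0).r == pytest.approx(1.0)

    def test_twelve_taxon_report_lists_all_taxa(self):
        params = EvolSimParams(
            group_structure=[self.FIG3_ABBREVIATIONS[:6], self.FIG3_ABBREVIATIONS[6:]],
            pigment_noise=0.2,
            seed=3,
        )
        alignment, prof = simulate_coupled_dataset(params)
        report = tanglegram_report(prof, alignment, permutations=99, seed=3)
        assert sorted(report.taxa) == sorted(self.FIG3_ABBREVIATIONS)
        assert sorted(report.pigment_dendrogram.leaf_order()) == sorted(
            self.FIG3_ABBREVIATIONS
        )
        assert sorted(report.sequence_dendrogram.leaf_order()) == sorted(
            self.FIG3_ABBREVIATIONS
        )

    def test_label_permutation_equivariance(self, rng):
        params = EvolSimParams(
            group_structure=[["a", "b", "c"], ["d", "e", "f"]],
            pigment_noise=0.3,
            seed=11,
        )
        alignment, prof = simulate_coupled_dataset(params)
        report1 = tanglegram_report(prof, alignment, permutations=99, seed=2)
        # shuffle taxon order in both inputs
        order = rng.permutation(len(prof))
        prof2 = prof.iloc[order]
        idx = {n: i for i, n in enumerate(alignment.names)}
        names2 = [prof2.index[i] for i in range(len(prof2))]
        alignment2 = type(alignment)(
            names=names2, sequences=[alignment.sequences[idx[n]] for n in names2]
        )
        report2 = tanglegram_report(prof2, alignment2, permutations=99, seed=2)
        assert report2.mantel.r == pytest.approx(report1.mantel.r)
        # distances agree once aligned back to the original label order
        np.testing.assert_allclose(
            report2.pigment_distances.reordered(report1.taxa).values,
            report1.pigment_distances.values,
        )
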