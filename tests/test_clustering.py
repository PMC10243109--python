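"""Packed Hamming distances, per-bucket clustering, global labels, medoid."""

import numpy as np
import pytest

from hdspec import (
    bucket_distance_matrix,
    cluster_bucket,
    hamming_distance,
    pack_bits,
    representative_spectrum,
    run_all_buckets,
    unpack_bits,
)
from hdspec.bucketing import BucketKey
from hdspec.io import RawSpectrum
from conftest import make_quantized


def random_hv(rng, dim):
    return pack_bits(rng.integers(0, 2, dim))


def naive_distance(a, b):
    """Per-bit loop oracle for the packed-word distance."""
    bits_a, bits_b = unpack_bits(a), unpack_bits(b)
    return sum(int(x != y) for x, y in zip(bits_a, bits_b)) / a.dim


class TestHammingDistance:
    def test_self_distance_zero(self, rng):
        hv = random_hv(rng, 256)
        assert hamming_distance(hv, hv) == 0.0

    def test_complement_distance_one(self, rng):
        hv = random_hv(rng, 100)  # D not a multiple of 32: padding must not leak
        assert hamming_distance(hv, hv.complement()) == 1.0

    @pytest.mark.parametrize("dim", [128, 2048])
    def test_matches_per_bit_oracle(self, rng, dim):
        for _ in range(25):
            a, b = random_hv(rng, dim), random_hv(rng, dim)
            assert hamming_distance(a, b) == naive_distance(a, b)

    def test_dimension_mismatch_fatal(self, rng):
        with pytest.raises(ValueError):
            hamming_distance(random_hv(rng, 64), random_hv(rng, 128))


class TestBucketDistanceMatrix:
    def test_two_identical(self, rng):
        hv = random_hv(rng, 128)
        np.testing.assert_array_equal(bucket_distance_matrix([hv, hv]), [0.0])

    def test_contains_complement_pair(self, rng):
        hv = random_hv(rng, 128)
        condensed = bucket_distance_matrix([hv, hv.complement(), random_hv(rng, 128)])
        assert condensed[0] == 1.0

    def test_small_buckets_empty(self, rng):
        assert bucket_distance_matrix([]).size == 0
        assert bucket_distance_matrix([random_hv(rng, 64)]).size == 0

    def test_matches_brute_force(self, rng):
        hvs = [random_hv(rng, 160) for _ in range(10)]
        condensed = bucket_distance_matrix(hvs)
        k = 0
        for i in range(10):
            for j in range(i + 1, 10):
                assert condensed[k] == hamming_distance(hvs[i], hvs[j])
                k += 1
        assert k == condensed.size


def two_pairs_matrix():
    """4 points: {0,1} at distance 0.05, {2,3} at 0.08, pairs 0.5 apart."""
    full = np.array(
        [
            [0.0, 0.05, 0.5, 0.5],
            [0.05, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.08],
            [0.5, 0.5, 0.08, 0.0],
        ]
    )
    return full[np.triu_indices(4, k=1)]


class TestClusterBucket:
    @pytest.mark.parametrize("algorithm", ["hierarchical", "dbscan"])
    def test_close_pair_merges(self, algorithm):
        labels = cluster_bucket(np.array([0.1]), 2, algorithm=algorithm, eps=0.25)
        np.testing.assert_array_equal(labels, [0, 0])

    @pytest.mark.parametrize("algorithm", ["hierarchical", "dbscan"])
    def test_all_far_apart_noise(self, algorithm, rng):
        condensed = np.full(6, 0.9)
        labels = cluster_bucket(condensed, 4, algorithm=algorithm, eps=0.25)
        np.testing.assert_array_equal(labels, [-1, -1, -1, -1])

    @pytest.mark.parametrize("algorithm", ["hierarchical", "dbscan"])
    def test_two_tight_pairs(self, algorithm):
        labels = cluster_bucket(two_pairs_matrix(), 4, algorithm=algorithm, eps=0.25)
        assert labels[0] == labels[1] != labels[2]
        assert labels[2] == labels[3]
        assert set(labels) == {0, 1}

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            cluster_bucket(np.array([0.1]), 2, eps=1.5)

    def test_complete_linkage_bounds_intra_cluster_distance(self, rng):
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(3, 30))
            condensed = rng.uniform(0, 1, n * (n - 1) // 2)
            labels = cluster_bucket(condensed, n, algorithm="hierarchical", eps=0.3)
            full = squareform(condensed)
            for label in set(labels) - {-1}:
                members = np.flatnonzero(labels == label)
                assert full[np.ix_(members, members)].max() <= 0.3

    def test_dbscan_chains_stay_connected(self, rng):
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(3, 30))
            condensed = rng.uniform(0, 1, n * (n - 1) // 2)
            labels = cluster_bucket(condensed, n, algorithm="dbscan", eps=0.3)
            full = squareform(condensed)
            for label in set(labels) - {-1}:
                members = np.flatnonzero(labels == label)
                assert len(members) >= 2
                for i in members:
                    others = members[members != i]
                    assert full[i, others].min() <= 0.3

    @pytest.mark.parametrize("algorithm", ["hierarchical", "dbscan"])
    def test_order_invariance_up_to_relabeling(self, algorithm, rng):
        """Permuting bucket members permutes labels consistently (tie-free matrix)."""
        from scipy.spatial.distance import squareform

        n = 12
        points = rng.uniform(0, 1, (n, 2))
        full = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1)) / 2
        condensed = full[np.triu_indices(n, k=1)]
        assert len(np.unique(condensed)) == condensed.size  # no ties
        labels = cluster_bucket(condensed, n, algorithm=algorithm, eps=0.2)
        perm = rng.permutation(n)
        permuted_full = full[np.ix_(perm, perm)]
        permuted = cluster_bucket(permuted_full[np.triu_indices(n, k=1)], n, algorithm=algorithm, eps=0.2)
        # same partition: co-membership must agree
        same = labels[:, None] == labels[None]
        noise = (labels == -1)[:, None] | (labels == -1)[None]
        same_p = permuted[:, None] == permuted[None]
        noise_p = (permuted == -1)[:, None] | (permuted == -1)[None]
        np.testing.assert_array_equal(
            (same & ~noise), (same_p & ~noise_p)[np.ix_(np.argsort(perm), np.argsort(perm))]
        )
        np.testing.assert_array_equal(labels == -1, (permuted == -1)[np.argsort(perm)])


class TestRunAllBuckets:
    def build(self, rng, groups, dim=256):
        """groups: list of (bucket_key, n_tight_members). Returns table, hvs, specs."""
        table, hvs, specs = {}, [], []
        for key, n in groups:
            ordinals = []
            base = unpack_bits(random_hv(rng, dim))
            for _ in range(n):
                bits = base.copy()
                flip = rng.choice(dim, size=3, replace=False)
                bits[flip] ^= 1
                ordinals.append(len(hvs))
                hvs.append(pack_bits(bits))
                specs.append(make_quantized(rng, 100, 16, identifier=f"s{len(specs)}"))
            table[key] = ordinals
        return table, hvs, specs

    def test_globally_unique_labels(self, rng):
        table, hvs, specs = self.build(rng, [(BucketKey(2, 10), 3), (BucketKey(2, 20), 2)])
        assignments = run_all_buckets(table, hvs, specs, eps=0.25)
        labels = {a.cluster_label for a in assignments if a.cluster_label >= 0}
        assert labels == {0, 1}
        by_label = {}
        for a in assignments:
            if a.cluster_label >= 0:
                by_label.setdefault(a.cluster_label, set()).add(a.bucket)
        assert all(len(buckets) == 1 for buckets in by_label.values())

    def test_empty_table(self, rng):
        assert run_all_buckets({}, [], []) == []

    def test_singleton_bucket_is_noise(self, rng):
        table, hvs, specs = self.build(rng, [(BucketKey(2, 10), 1)])
        (assignment,) = run_all_buckets(table, hvs, specs)
        assert assignment.cluster_label == -1

    def test_label_count_equals_sum_of_bucket_clusters(self, rng):
        groups = [(BucketKey(2, i), int(rng.integers(1, 6))) for i in range(8)]
        table, hvs, specs = self.build(rng, groups)
        assignments = run_all_buckets(table, hvs, specs, eps=0.25)
        n_global = len({a.cluster_label for a in assignments if a.cluster_label >= 0})
        expected = sum(1 for _, n in groups if n >= 2)  # each tight group -> one cluster
        assert n_global == expected

    def test_worker_count_does_not_change_result(self, rng):
        groups = [(BucketKey(2, i), int(rng.integers(1, 6))) for i in range(6)]
        table, hvs, specs = self.build(rng, groups)
        serial = run_all_buckets(table, hvs, specs, workers=1)
        parallel = run_all_buckets(table, hvs, specs, workers=2)
        assert [(a.identifier, a.cluster_label) for a in serial] == [
            (a.identifier, a.cluster_label) for a in parallel
        ]


class TestRepresentative:
    def raw(self, identifier):
        return RawSpectrum(identifier, 500.0, 2, np.array([110.0]), np.array([1.0]))

    def test_cluster_of_one(self, rng):
        raw = self.raw("only")
        assert representative_spectrum([random_hv(rng, 64)], [raw]) is raw

    def test_medoid_matches_brute_force(self, rng):
        hvs = [random_hv(rng, 256) for _ in range(7)]
        raws = [self.raw(str(i)) for i in range(7)]
        totals = [sum(hamming_distance(hvs[i], h) for h in hvs) for i in range(7)]
        expected = raws[int(np.argmin(totals))]
        assert representative_spectrum(hvs, raws) is expected

    def test_midpoint_member_wins(self, rng):
        base = rng.integers(0, 2, 128).astype(np.uint8)
        a, b = base.copy(), base.copy()
        a[:8] ^= 1
        b[8:16] ^= 1  # disjoint flips: base sits between a and b
        hvs = [pack_bits(a), pack_bits(base), pack_bits(b)]
        raws = [self.raw("a"), self.raw("mid"), self.raw("b")]
        assert representative_spectrum(hvs, raws).identifier == "mid"
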