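"""Per-bucket Hamming distance matrices and clustering.

Distances between packed hypervectors are normalized Hamming distances:
popcount(a XOR b) / D, computed word-wise on the packed representation
(ceil(D/32) word operations per pair). Each bucket is clustered
independently with either hierarchical complete linkage cut at a
distance threshold, or DBSCAN on the precomputed matrix; cluster labels
are then offset to global uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

from .bucketing import BucketKey, BucketTable
from .encoding import PackedHV
from .io import RawSpectrum
from .preprocess import QuantizedSpectrum

ALGORITHMS = ("hierarchical", "dbscan")


@dataclass
class ClusterAssignment:
    """Final per-spectrum record: bucket key and global cluster label.

    ``bucket is None`` and ``cluster_label == -1`` mark spectra rejected
    before clustering; label -1 otherwise marks noise/singletons.
    """

    identifier: str
    precursor_charge: int
    precursor_mz: float
    bucket: Optional[BucketKey]
    cluster_label: int


def hamming_distance(a: PackedHV, b: PackedHV) -> float:
    """Normalized Hamming distance popcount(a XOR b) / D, in [0, 1]."""
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} != {b.dim}")
    return int(np.bitwise_count(a.words ^ b.words).sum()) / a.dim


def _stack_words(hvs: Sequence[PackedHV]) -> np.ndarray:
    dims = {hv.dim for hv in hvs}
    if len(dims) > 1:
        raise ValueError("mixed hypervector dimensions in one bucket")
    return np.vstack([hv.words for hv in hvs])


def bucket_distance_matrix(hvs: Sequence[PackedHV]) -> np.ndarray:
    """Condensed (upper-triangular) pairwise distance matrix of a bucket.

    Returns an array of length n(n-1)/2; empty for n < 2.
    """
    n = len(hvs)
    if n < 2:
        return np.empty(0, dtype=np.float64)
    words = _stack_words(hvs)
    dim = hvs[0].dim
    parts = [
        np.bitwise_count(words[i] ^ words[i + 1 :]).sum(axis=1)
        for i in range(n - 1)
    ]
    return np.concatenate(parts).astype(np.float64) / dim


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Make non-noise labels contiguous from 0 in order of first occurrence."""
    out = np.full(labels.shape, -1, dtype=np.int64)
    mapping: Dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_bucket(
    condensed: np.ndarray,
    n: int,
    algorithm: str = "hierarchical",
    eps: float = 0.25,
) -> np.ndarray:
    """Cluster one bucket from its condensed distance matrix.

    hierarchical: complete linkage, dendrogram cut at height ``eps``,
    then clusters of size 1 relabeled -1 so "clustered" means the same
    thing for both algorithms. dbscan: precomputed distances,
    ``min_samples=2`` (a point plus one neighbor), noise -> -1. Labels
    are local to the bucket and contiguous from 0.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if n < 2:
        return np.full(n, -1, dtype=np.int64)
    if condensed.size != n * (n - 1) // 2:
        raise ValueError("condensed length must be n(n-1)/2")

    if algorithm == "hierarchical":
        labels = fcluster(linkage(condensed, method="complete"), t=eps, criterion="distance")
        labels = labels.astype(np.int64)
        uniq, counts = np.unique(labels, return_counts=True)
        singletons = set(uniq[counts == 1])
        labels = np.array([-1 if l in singletons else l for l in labels])
    else:
        labels = DBSCAN(eps=eps, min_samples=2, metric="precomputed").fit_predict(
            squareform(condensed)
        )
    return _relabel(np.asarray(labels))


def run_all_buckets(
    table: BucketTable,
    hvs: Sequence[PackedHV],
    spectra: Sequence[QuantizedSpectrum],
    algorithm: str = "hierarchical",
    eps: float = 0.25,
    workers: int = 1,
) -> List[ClusterAssignment]:
    """Cluster every bucket and offset labels to global uniqueness.

    Buckets of size 1 yield label -1. Buckets are processed in sorted
    key order and label offsets assigned afterwards, so the worker count
    never changes the result.
    """
    keys = sorted(table)

    def one(key: BucketKey) -> np.ndarray:
        ordinals = table[key]
        condensed = bucket_distance_matrix([hvs[i] for i in ordinals])
        return cluster_bucket(condensed, len(ordinals), algorithm=algorithm, eps=eps)

    if workers == 1:
        local = [one(k) for k in keys]
    else:
        local = Parallel(n_jobs=workers)(delayed(one)(k) for k in keys)

    assignments: List[ClusterAssignment] = []
    offset = 0
    for key, labels in zip(keys, local):
        for ordinal, label in zip(table[key], labels):
            spec = spectra[ordinal]
            assignments.append(
                ClusterAssignment(
                    identifier=spec.identifier,
                    precursor_charge=spec.precursor_charge,
                    precursor_mz=spec.precursor_mz,
                    bucket=key,
                    cluster_label=-1 if label == -1 else label + offset,
                )
            )
        if labels.size:
            offset += int(labels.max()) + 1
    return assignments


def representative_spectrum(
    member_hvs: Sequence[PackedHV], member_raw: Sequence[RawSpectrum]
) -> RawSpectrum:
    """Medoid representative of a cluster.

    Returns the member whose hypervector minimizes the summed Hamming
    distance to all other members; ties go to the lowest ordinal.
    """
    if len(member_hvs) != len(member_raw) or not member_hvs:
        raise ValueError("need equal-length, non-empty member lists")
    if len(member_hvs) == 1:
        return member_raw[0]
    words = _stack_words(member_hvs)
    totals = np.array(
        [np.bitwise_count(words[i] ^ words).sum() for i in range(len(member_hvs))]
    )
    return member_raw[int(np.argmin(totals))]
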