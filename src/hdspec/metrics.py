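"""Clustering-quality metrics.

Three quantities summarize a clustering against (optionally partial)
peptide identifications:

* clustered spectra ratio — spectra in clusters of size >= 2 over all
  input spectra (rejected ones included in the denominator);
* incorrect clustering ratio — clustered-and-identified spectra whose
  peptide deviates from their cluster's most frequent peptide, over all
  clustered-and-identified spectra;
* completeness — 1 - H(cluster | peptide) / H(cluster), in nats, over
  clustered-and-identified spectra; 1 when every peptide's spectra sit
  in a single cluster.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .clustering import ClusterAssignment


def _clusters(assignments: Sequence[ClusterAssignment]) -> Dict[int, List[ClusterAssignment]]:
    """Group by global label, keeping only clusters of size >= 2."""
    groups: Dict[int, List[ClusterAssignment]] = defaultdict(list)
    for a in assignments:
        if a.cluster_label >= 0:
            groups[a.cluster_label].append(a)
    return {label: members for label, members in groups.items() if len(members) >= 2}


def clustered_ratio(assignments: Sequence[ClusterAssignment]) -> float:
    """Fraction of all spectra that sit in clusters of size >= 2."""
    if not assignments:
        return 0.0
    n_clustered = sum(len(m) for m in _clusters(assignments).values())
    return n_clustered / len(assignments)


def _identified_pairs(
    assignments: Sequence[ClusterAssignment], peptide_labels: Mapping[str, str]
) -> List[Tuple[int, str]]:
    """(cluster label, peptide) for clustered-and-identified spectra."""
    pairs = []
    for label, members in _clusters(assignments).items():
        for a in members:
            peptide = peptide_labels.get(a.identifier)
            if peptide is not None:
                pairs.append((label, peptide))
    return pairs


def incorrect_ratio(
    assignments: Sequence[ClusterAssignment], peptide_labels: Mapping[str, str]
) -> float:
    """Fraction of clustered-and-identified spectra off their cluster's majority peptide.

    Majority ties are immaterial: the incorrect count is the same for
    any maximal peptide choice. Returns 0.0 when no clustered spectrum
    is identified.
    """
    pairs = _identified_pairs(assignments, peptide_labels)
    if not pairs:
        return 0.0
    per_cluster: Dict[int, Counter] = defaultdict(Counter)
    for label, peptide in pairs:
        per_cluster[label][peptide] += 1
    n_incorrect = sum(
        sum(counts.values()) - max(counts.values()) for counts in per_cluster.values()
    )
    return n_incorrect / len(pairs)


def completeness(
    assignments: Sequence[ClusterAssignment], peptide_labels: Mapping[str, str]
) -> float:
    """1 - H(C|P)/H(C) from empirical joint counts over clustered-and-identified spectra.

    Entropies in nats; by convention 1.0 when H(C) = 0 (zero or one
    cluster carries all identified spectra).
    """
    pairs = _identified_pairs(assignments, peptide_labels)
    if not pairs:
        return 1.0
    clusters = sorted({c for c, _ in pairs})
    peptides = sorted({p for _, p in pairs})
    joint = np.zeros((len(clusters), len(peptides)))
    c_index = {c: i for i, c in enumerate(clusters)}
    p_index = {p: j for j, p in enumerate(peptides)}
    for c, p in pairs:
        joint[c_index[c], p_index[p]] += 1
    joint /= joint.sum()

    def entropy(prob: np.ndarray) -> float:
        prob = prob[prob > 0]
        return float(-(prob * np.log(prob)).sum())

    h_c = entropy(joint.sum(axis=1))
    if h_c == 0.0:
        return 1.0
    # H(C|P) = H(C,P) - H(P)
    h_c_given_p = entropy(joint.ravel()) - entropy(joint.sum(axis=0))
    return 1.0 - h_c_given_p / h_c


def cluster_size_histogram(
    assignments: Sequence[ClusterAssignment], edges: Sequence[int] = (5, 500)
) -> Dict[str, int]:
    """Count clusters (size >= 2) into size ranges bounded by ``edges``.

    With edges (5, 500) the ranges are "2-5", "6-500", "501+". Returns
    an empty mapping when there are no clusters; counts always sum to
    the number of clusters.
    """
    sizes = [len(m) for m in _clusters(assignments).values()]
    if not sizes:
        return {}
    edges = sorted(edges)
    bounds = [2] + [e + 1 for e in edges]
    names = [
        f"{lo}-{hi}" for lo, hi in zip(bounds[:-1], [e for e in edges])
    ] + [f"{bounds[-1]}+"]
    counts = dict.fromkeys(names, 0)
    for size in sizes:
        counts[names[int(np.searchsorted(edges, size))]] += 1
    return counts


@dataclass
class MetricsReport:
    """Bundle of all quality metrics for one clustering run."""

    n_total: int
    n_clustered: int
    clustered_ratio: float
    n_incorrect: Optional[int] = None
    incorrect_ratio: Optional[float] = None
    completeness: Optional[float] = None
    cluster_size_histogram: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_clustered": self.n_clustered,
            "clustered_ratio": self.clustered_ratio,
            "n_incorrect": self.n_incorrect,
            "incorrect_ratio": self.incorrect_ratio,
            "completeness": self.completeness,
            "cluster_size_histogram": self.cluster_size_histogram,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def compute_report(
    assignments: Sequence[ClusterAssignment],
    peptide_labels: Optional[Mapping[str, str]] = None,
    edges: Sequence[int] = (5, 500),
) -> MetricsReport:
    """Compute every metric; label-dependent ones are None without labels."""
    clusters = _clusters(assignments)
    n_clustered = sum(len(m) for m in clusters.values())
    report = MetricsReport(
        n_total=len(assignments),
        n_clustered=n_clustered,
        clustered_ratio=clustered_ratio(assignments),
        cluster_size_histogram=cluster_size_histogram(assignments, edges=edges),
    )
    if peptide_labels is not None:
        pairs = _identified_pairs(assignments, peptide_labels)
        report.incorrect_ratio = incorrect_ratio(assignments, peptide_labels)
        report.n_incorrect = round(report.incorrect_ratio * len(pairs))
        report.completeness = completeness(assignments, peptide_labels)
    return report
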