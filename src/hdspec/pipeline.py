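"""End-to-end orchestration: preprocess -> bucket -> encode -> distance -> cluster.

One seed governs the codebook, the majority tie-break vector and the
synthetic-data generator, and per-bucket work is offset deterministically,
so a run is reproducible byte-for-byte regardless of worker count or
batch size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

from . import io as sio
from .bucketing import assign_buckets
from .clustering import ClusterAssignment, run_all_buckets
from .encoding import encode_batch, generate_codebook
from .metrics import MetricsReport, compute_report
from .preprocess import PreprocessParams, Rejection, preprocess_spectrum, vectorize_quantize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one clustering run."""

    inputs: List[Path]
    output: Path
    dim: int = 2048
    eps: float = 0.25
    algorithm: str = "hierarchical"
    charges: Tuple[int, ...] = (2, 3)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    seed: int = 0
    flip_id: Optional[int] = None
    flip_level: Optional[int] = None
    batch_size: int = 2048
    workers: int = 1
    split_by_charge: bool = True
    labels_path: Optional[Path] = None

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input MGF is required")
        if not 0 < self.eps < 1:
            raise ValueError("eps must be in (0, 1)")
        if self.dim < 32:
            raise ValueError("dim must be >= 32")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inputs"] = [str(p) for p in self.inputs]
        d["output"] = str(self.output)
        d["labels_path"] = None if self.labels_path is None else str(self.labels_path)
        return d


@dataclass
class PipelineResult:
    assignments: List[ClusterAssignment]
    report: MetricsReport
    summary: dict


def _collect_mgf_paths(inputs: Sequence[Path]) -> List[Path]:
    paths: List[Path] = []
    for entry in inputs:
        entry = Path(entry)
        if entry.is_dir():
            paths.extend(sorted(entry.glob("*.mgf")))
        else:
            paths.append(entry)
    return paths


def run_pipeline(
    config: PipelineConfig, peptide_labels: Optional[Mapping[str, str]] = None
) -> PipelineResult:
    """Run the five-step flow and write the assignment TSV.

    Every parsed spectrum gets exactly one output row; spectra filtered
    by charge, rejected by preprocessing or with a degenerate precursor
    keep bucket -1 / label -1. When peptide labels are available (from
    ``config.labels_path`` or passed directly) the label-dependent
    quality metrics are computed too.
    """
    config.validate()
    paths = _collect_mgf_paths(config.inputs)

    stats = sio.ParseStats()
    raw = list(sio.read_mgf_many(paths, allowed_charges=None, stats=stats))

    allowed = frozenset(config.charges)
    retained, quantized, side_rows = [], [], []
    reject_counts: dict = {}

    def side(spectrum) -> None:
        side_rows.append(
            ClusterAssignment(
                identifier=spectrum.identifier,
                precursor_charge=spectrum.precursor_charge,
                precursor_mz=spectrum.precursor_mz,
                bucket=None,
                cluster_label=-1,
            )
        )

    for spectrum in raw:
        if spectrum.precursor_charge not in allowed:
            reject_counts["charge_filtered"] = reject_counts.get("charge_filtered", 0) + 1
            side(spectrum)
            continue
        result = preprocess_spectrum(spectrum, config.preprocess)
        if isinstance(result, Rejection):
            reject_counts[result.reason] = reject_counts.get(result.reason, 0) + 1
            side(spectrum)
            continue
        retained.append(result)
        quantized.append(vectorize_quantize(result, config.preprocess))

    table, degenerate = assign_buckets(quantized, split_by_charge=config.split_by_charge)
    for ordinal in degenerate:
        reject_counts["degenerate_precursor"] = reject_counts.get("degenerate_precursor", 0) + 1
        side(quantized[ordinal])

    if table:
        codebook = generate_codebook(
            dim=config.dim,
            n_ids=config.preprocess.n_bins,
            n_levels=config.preprocess.q_levels,
            seed=config.seed,
            flip_id=config.flip_id,
            flip_level=config.flip_level,
        )
        hvs = encode_batch(quantized, codebook, batch_size=config.batch_size)
        clustered = run_all_buckets(
            table,
            hvs,
            quantized,
            algorithm=config.algorithm,
            eps=config.eps,
            workers=config.workers,
        )
    else:
        logger.warning("no spectra survived preprocessing; writing empty outputs")
        clustered = []

    # stable output order: retained spectra in input order, then side rows
    ordinals_in_order = [i for key in sorted(table) for i in table[key]]
    by_ordinal = dict(zip(ordinals_in_order, clustered))
    assignments = [by_ordinal[i] for i in range(len(quantized)) if i in by_ordinal]
    assignments.extend(side_rows)

    sio.write_assignments(assignments, config.output)
    sidecar = Path(str(config.output) + ".config.json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    if peptide_labels is None and config.labels_path is not None:
        peptide_labels = sio.read_peptide_labels(config.labels_path)
    report = compute_report(assignments, peptide_labels)

    n_clusters = len({a.cluster_label for a in assignments if a.cluster_label >= 0})
    summary = {
        "n_files": len(paths),
        "n_blocks": stats.n_blocks,
        "n_parsed": stats.n_yielded,
        "n_parse_skipped": stats.n_skipped,
        "rejections": reject_counts,
        "n_retained": len(quantized),
        "n_buckets": len(table),
        "n_clusters": n_clusters,
        "clustered_ratio": report.clustered_ratio,
        "seed": config.seed,
    }
    logger.info("pipeline summary: %s", json.dumps(summary, sort_keys=True))
    return PipelineResult(assignments=assignments, report=report, summary=summary)
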