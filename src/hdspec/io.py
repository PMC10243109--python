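"""Reading MGF peak lists and writing cluster-assignment tables.

The reader accepts the two MGF dialects found in the wild ("CHARGE=2+"
and "CHARGE=2"; PEPMASS with an optional second intensity number) and
recovers from malformed blocks by skipping them, so one bad scan never
aborts a multi-gigabyte file. Accounting is exact: every ``BEGIN IONS``
block is either yielded, skipped (with a reason tally) or filtered by
charge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CHARGE_RE = re.compile(r"(\d+)\s*([+-]?)")
_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")

ASSIGNMENT_COLUMNS = [
    "identifier",
    "precursor_charge",
    "precursor_mz",
    "bucket",
    "cluster_label",
]


@dataclass
class RawSpectrum:
    """One parsed MGF entry.

    Attributes
    ----------
    identifier:
        TITLE line verbatim if present, else ``"<filename>:<ordinal>"``.
    precursor_mz:
        Precursor mass-to-charge in Da; positive.
    precursor_charge:
        Positive integer charge state.
    peak_mz, peak_intensity:
        Parallel arrays; ``peak_mz`` ascending after parsing.
    """

    identifier: str
    precursor_mz: float
    precursor_charge: int
    peak_mz: np.ndarray
    peak_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, dtype=np.float64)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=np.float64)
        if self.peak_mz.shape != self.peak_intensity.shape:
            raise ValueError("peak_mz and peak_intensity must be parallel arrays")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_mz.size)


@dataclass
class ParseStats:
    """Per-file block accounting: n_blocks == n_yielded + n_skipped + n_charge_filtered."""

    n_blocks: int = 0
    n_yielded: int = 0
    n_charge_filtered: int = 0
    n_skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)

    def _skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


def _parse_charge(value: str) -> Optional[int]:
    m = _CHARGE_RE.search(value)
    if m is None:
        return None
    z = int(m.group(1))
    return z if z > 0 else None


def _parse_pepmass(value: str) -> Optional[float]:
    m = _FLOAT_RE.search(value)
    if m is None:
        return None
    mz = float(m.group(0))
    return mz if mz > 0 else None


def _finish_block(
    header: dict,
    mz: list,
    intensity: list,
    identifier: str,
    stats: ParseStats,
) -> Optional[RawSpectrum]:
    pepmass = header.get("PEPMASS")
    charge = header.get("CHARGE")
    precursor_mz = _parse_pepmass(pepmass) if pepmass is not None else None
    if precursor_mz is None:
        stats._skip("bad_pepmass")
        return None
    precursor_charge = _parse_charge(charge) if charge is not None else None
    if precursor_charge is None:
        # The bucket formula needs a charge; spectra without one are dropped.
        stats._skip("bad_charge")
        return None
    if not mz:
        stats._skip("no_peaks")
        return None
    mz_arr = np.asarray(mz, dtype=np.float64)
    int_arr = np.asarray(intensity, dtype=np.float64)
    order = np.argsort(mz_arr, kind="stable")
    return RawSpectrum(
        identifier=identifier,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        peak_mz=mz_arr[order],
        peak_intensity=int_arr[order],
    )


def read_mgf(
    path: str | Path,
    allowed_charges: Optional[Iterable[int]] = frozenset({2, 3}),
    stats: Optional[ParseStats] = None,
) -> Iterator[RawSpectrum]:
    """Yield :class:`RawSpectrum` records from one MGF file.

    Parameters
    ----------
    path:
        MGF file; missing file raises ``FileNotFoundError``.
    allowed_charges:
        Keep only spectra whose precursor charge is in this set;
        ``None`` keeps every parseable charge.
    stats:
        Optional accounting object, filled in place.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if stats is None:
        stats = ParseStats()
    allowed = None if allowed_charges is None else frozenset(allowed_charges)
    stem = path.stem

    in_block = False
    header: dict = {}
    mz: list = []
    intensity: list = []
    with path.open("r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                stats.n_blocks += 1
                header, mz, intensity = {}, [], []
                continue
            if not in_block:
                continue
            if line == "END IONS":
                in_block = False
                identifier = header.get("TITLE") or f"{stem}:{stats.n_blocks}"
                spectrum = _finish_block(header, mz, intensity, identifier, stats)
                if spectrum is None:
                    continue
                if allowed is not None and spectrum.precursor_charge not in allowed:
                    stats.n_charge_filtered += 1
                    continue
                stats.n_yielded += 1
                yield spectrum
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                header[key.strip().upper()] = value.strip()
                continue
            fields = line.split()
            try:
                peak_mz = float(fields[0])
                peak_int = float(fields[1]) if len(fields) > 1 else 0.0
            except (ValueError, IndexError):
                continue  # stray non-numeric line inside a block
            if peak_mz > 0 and peak_int >= 0:
                mz.append(peak_mz)
                intensity.append(peak_int)
    if in_block:
        # File truncated mid-block.
        stats._skip("truncated_block")
    if stats.n_skipped:
        logger.warning("%s: skipped %d malformed block(s): %s", path, stats.n_skipped, stats.skip_reasons)


def read_mgf_many(
    paths: Sequence[str | Path],
    allowed_charges: Optional[Iterable[int]] = frozenset({2, 3}),
    stats: Optional[ParseStats] = None,
) -> Iterator[RawSpectrum]:
    """Chain :func:`read_mgf` over several files, sharing one stats object."""
    for path in paths:
        yield from read_mgf(path, allowed_charges=allowed_charges, stats=stats)


def format_bucket(bucket) -> str:
    """Serialize a bucket key as ``"charge:index"``; ``-1`` marks rejected spectra."""
    if bucket is None:
        return "-1"
    return f"{bucket[0]}:{bucket[1]}"


def parse_bucket(text: str):
    if text == "-1":
        return None
    charge, _, index = text.partition(":")
    return (int(charge), int(index))


def write_assignments(assignments, path: str | Path) -> None:
    """Write the cluster assignment table as TSV.

    One row per input spectrum, including rejected spectra (bucket ``-1``,
    cluster_label ``-1``); columns ``identifier, precursor_charge,
    precursor_mz, bucket, cluster_label``.
    """
    rows = [
        {
            "identifier": a.identifier,
            "precursor_charge": a.precursor_charge,
            "precursor_mz": repr(a.precursor_mz),
            "bucket": format_bucket(a.bucket),
            "cluster_label": a.cluster_label,
        }
        for a in assignments
    ]
    frame = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path):
    """Read back a table written by :func:`write_assignments`."""
    from .clustering import ClusterAssignment

    frame = pd.read_csv(path, sep="\t", dtype={"identifier": str, "bucket": str})
    return [
        ClusterAssignment(
            identifier=row.identifier,
            precursor_charge=int(row.precursor_charge),
            precursor_mz=float(row.precursor_mz),
            bucket=parse_bucket(row.bucket),
            cluster_label=int(row.cluster_label),
        )
        for row in frame.itertuples(index=False)
    ]


def read_peptide_labels(path: str | Path) -> Mapping[str, str]:
    """Read a TSV mapping spectrum identifier -> peptide label."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "identifier" not in frame.columns or "peptide" not in frame.columns:
        raise ValueError("label table needs 'identifier' and 'peptide' columns")
    return dict(zip(frame["identifier"], frame["peptide"]))


def write_peptide_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"identifier": list(labels.keys()), "peptide": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
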