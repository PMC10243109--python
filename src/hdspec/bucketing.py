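"""Precursor-mass bucket division.

Each spectrum receives the integer bucket index

    floor( C * (m/z - 1.00794) / 1.0005079 )

where C is the precursor charge, 1.00794 Da the mass of the charge
carrier and 1.0005079 Da the spacing between adjacent clusters of
physically possible peptide masses. Distance matrices and clustering
are then confined to each bucket, cutting the all-pairs cost.
"""

from __future__ import annotations

import math
from typing import Dict, List, NamedTuple, Sequence, Tuple

from .preprocess import QuantizedSpectrum

CHARGE_CARRIER_MASS = 1.00794
PEPTIDE_MASS_SPACING = 1.0005079


class BucketKey(NamedTuple):
    charge: int
    index: int


BucketTable = Dict[BucketKey, List[int]]


def bucket_index(precursor_mz: float, charge: int, mode: str = "floor") -> int:
    """Integer bucket for a precursor; non-decreasing in m/z at fixed charge.

    ``mode="round"`` is available for sensitivity checks; the default
    floors, making buckets left-closed intervals of width 1.0005079 Da in
    charge-scaled neutral-mass space.
    """
    if precursor_mz < CHARGE_CARRIER_MASS:
        raise ValueError(f"degenerate precursor m/z {precursor_mz!r} < {CHARGE_CARRIER_MASS}")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    value = charge * (precursor_mz - CHARGE_CARRIER_MASS) / PEPTIDE_MASS_SPACING
    if mode == "floor":
        return math.floor(value)
    if mode == "round":
        return round(value)
    raise ValueError(f"unknown mode {mode!r}")


def assign_buckets(
    spectra: Sequence[QuantizedSpectrum],
    split_by_charge: bool = True,
    mode: str = "floor",
) -> Tuple[BucketTable, List[int]]:
    """Partition spectrum ordinals into buckets.

    Returns ``(table, rejected)`` where ``table`` maps :class:`BucketKey`
    to member ordinals sorted by ascending precursor m/z and ``rejected``
    lists ordinals with a degenerate precursor (m/z below the charge
    carrier mass). With ``split_by_charge`` (default) the key includes
    the charge; otherwise the charge slot is 0.
    """
    table: BucketTable = {}
    rejected: List[int] = []
    for ordinal, spec in enumerate(spectra):
        try:
            index = bucket_index(spec.precursor_mz, spec.precursor_charge, mode=mode)
        except ValueError:
            rejected.append(ordinal)
            continue
        key = BucketKey(spec.precursor_charge if split_by_charge else 0, index)
        table.setdefault(key, []).append(ordinal)
    for key, members in table.items():
        members.sort(key=lambda i: (spectra[i].precursor_mz, i))
    return table, rejected
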