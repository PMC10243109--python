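"""Binary hypervector encoding of quantized spectra.

Each spectrum is projected into a D-dimensional binary hypervector (HV):
an ID codebook **I** (one HV per m/z bin) and a level codebook **L**
(one HV per intensity level) are generated as random-flip chains, so
nearby bins/levels receive similar HVs. Each peak binds its ID and level
HVs by pointwise XOR, and the bound HVs are bundled by pointwise
majority into the spectrum HV:

    h = Majority( I_{bin_1} ^ L_{lvl_1}, ..., I_{bin_m} ^ L_{lvl_m} )

Even-vote ties are resolved by a seeded tie-break hypervector so the
encoding is fully deterministic. HVs are stored bit-packed, 32 bits per
machine word (position ``32*w + b``, little-endian within each word),
which is 8x smaller than byte-per-bit storage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .preprocess import QuantizedSpectrum

__all__ = [
    "PackedHV",
    "Codebook",
    "default_flip_count",
    "generate_codebook",
    "encode_spectrum",
    "encode_batch",
    "pack_bits",
    "unpack_bits",
    "save_codebook",
    "load_codebook",
]


@dataclass(frozen=True)
class PackedHV:
    """A D-bit binary hypervector as ceil(D/32) little-endian 32-bit words.

    Bits at positions >= D are zero.
    """

    words: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        words = np.ascontiguousarray(self.words, dtype=np.uint32)
        object.__setattr__(self, "words", words)
        if words.size != (self.dim + 31) // 32:
            raise ValueError("word count must be ceil(D/32)")

    @property
    def nbytes(self) -> int:
        return int(self.words.nbytes)

    def complement(self) -> "PackedHV":
        """Flip every one of the D bits (padding bits stay zero)."""
        return pack_bits(1 - unpack_bits(self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PackedHV):
            return NotImplemented
        return self.dim == other.dim and bool(np.array_equal(self.words, other.words))


def pack_bits(bits: np.ndarray) -> PackedHV:
    """Pack a 0/1 vector into a :class:`PackedHV`.

    Bit ``k`` of the input lands at word ``k // 32``, in-word position
    ``k % 32`` (little-endian). Non-binary input is a fatal error.
    """
    bits = np.asarray(bits)
    if bits.ndim != 1:
        raise ValueError("bits must be one-dimensional")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0/1")
    dim = int(bits.size)
    n_words = (dim + 31) // 32
    padded = np.zeros(n_words * 32, dtype=np.uint8)
    padded[:dim] = bits
    words = np.packbits(padded, bitorder="little").view("<u4")
    return PackedHV(words=words, dim=dim)


def unpack_bits(hv: PackedHV) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a uint8 0/1 vector of length D."""
    as_bytes = hv.words.astype("<u4", copy=False).view(np.uint8)
    return np.unpackbits(as_bytes, bitorder="little")[: hv.dim].copy()


def _pack_rows(bits: np.ndarray) -> np.ndarray:
    """Pack each row of an (n, D) 0/1 matrix into uint32 words."""
    n, dim = bits.shape
    n_words = (dim + 31) // 32
    padded = np.zeros((n, n_words * 32), dtype=np.uint8)
    padded[:, :dim] = bits
    return np.packbits(padded, axis=1, bitorder="little").view("<u4")


def default_flip_count(dim: int, n_entries: int) -> int:
    """Per-step flip count max(1, round(D / (2 n))).

    Walking the whole chain then flips about D/2 bits in total, so the
    first and last codebook entries approach orthogonality while
    consecutive entries stay nearly identical — the locality-preserving
    regime.
    """
    return max(1, round(dim / (2 * n_entries)))


@dataclass
class Codebook:
    """ID and level hypervector codebooks plus the majority tie-break HV.

    ``id_hvs`` is the f x D bit matrix **I** (one row per m/z bin),
    ``level_hvs`` the Q x D matrix **L** (row j-1 serves level j).
    Consecutive rows differ in exactly ``flip_id`` / ``flip_level``
    uniformly chosen bit positions. Same seed and parameters always
    reproduce a bit-identical codebook.
    """

    dim: int
    n_ids: int
    n_levels: int
    id_hvs: np.ndarray
    level_hvs: np.ndarray
    tie_hv: np.ndarray
    seed: int
    flip_id: int
    flip_level: int


def _flip_chain(rng: np.random.Generator, n: int, dim: int, flips: int) -> np.ndarray:
    hvs = np.empty((n, dim), dtype=np.uint8)
    hvs[0] = rng.integers(0, 2, size=dim, dtype=np.uint8)
    for k in range(1, n):
        hvs[k] = hvs[k - 1]
        positions = rng.choice(dim, size=flips, replace=False)
        hvs[k, positions] ^= 1
    return hvs


def generate_codebook(
    dim: int = 2048,
    n_ids: int = 27980,
    n_levels: int = 16,
    seed: int = 0,
    flip_id: Optional[int] = None,
    flip_level: Optional[int] = None,
) -> Codebook:
    """Generate the ID/level codebooks as seeded random-flip chains.

    The first HV of each chain is uniform random; every successive HV
    flips exactly ``flip_id`` (resp. ``flip_level``) distinct, uniformly
    chosen bit positions of its predecessor. Flip positions are sampled
    without replacement, independently per step.
    """
    if dim < 32:
        raise ValueError("dim must be >= 32")
    if n_ids < 2 or n_levels < 2:
        raise ValueError("n_ids and n_levels must be >= 2")
    if flip_id is None:
        flip_id = default_flip_count(dim, n_ids)
    if flip_level is None:
        flip_level = default_flip_count(dim, n_levels)
    for name, flips in (("flip_id", flip_id), ("flip_level", flip_level)):
        if not 1 <= flips <= dim:
            raise ValueError(f"{name} must be in [1, D], got {flips}")

    id_ss, level_ss, tie_ss = np.random.SeedSequence(seed).spawn(3)
    id_hvs = _flip_chain(np.random.default_rng(id_ss), n_ids, dim, flip_id)
    level_hvs = _flip_chain(np.random.default_rng(level_ss), n_levels, dim, flip_level)
    tie_hv = np.random.default_rng(tie_ss).integers(0, 2, size=dim, dtype=np.uint8)
    return Codebook(
        dim=dim,
        n_ids=n_ids,
        n_levels=n_levels,
        id_hvs=id_hvs,
        level_hvs=level_hvs,
        tie_hv=tie_hv,
        seed=seed,
        flip_id=flip_id,
        flip_level=flip_level,
    )


def _check_ranges(spec: QuantizedSpectrum, cb: Codebook) -> None:
    if spec.bins.size == 0:
        raise ValueError(f"{spec.identifier}: empty quantized spectrum")
    if spec.bins.min() < 0 or spec.bins.max() >= cb.n_ids:
        raise ValueError(f"{spec.identifier}: bin index outside [0, {cb.n_ids})")
    if spec.levels.min() < 1 or spec.levels.max() > cb.n_levels:
        raise ValueError(f"{spec.identifier}: level outside [1, {cb.n_levels}]")


def _majority(vote_counts: np.ndarray, n_votes, tie_hv: np.ndarray) -> np.ndarray:
    """Pointwise majority of n_votes bound HVs; exact ties take the tie HV bit."""
    doubled = 2 * vote_counts
    out = (doubled > n_votes).astype(np.uint8)
    tie = doubled == n_votes
    out[tie] = np.broadcast_to(tie_hv, vote_counts.shape)[tie]
    return out


def encode_spectrum(spec: QuantizedSpectrum, cb: Codebook) -> PackedHV:
    """Encode one quantized spectrum into a packed hypervector."""
    _check_ranges(spec, cb)
    bound = cb.id_hvs[spec.bins] ^ cb.level_hvs[spec.levels - 1]
    bits = _majority(bound.sum(axis=0, dtype=np.int64), spec.bins.size, cb.tie_hv)
    return pack_bits(bits)


def encode_batch(
    specs: Sequence[QuantizedSpectrum],
    cb: Codebook,
    batch_size: int = 2048,
) -> List[PackedHV]:
    """Encode many spectra, ``batch_size`` at a time.

    Bit-identical to mapping :func:`encode_spectrum` over the list for
    any batch size; batching only amortizes the codebook gathers.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out: List[PackedHV] = []
    for start in range(0, len(specs), batch_size):
        chunk = specs[start : start + batch_size]
        for spec in chunk:
            _check_ranges(spec, cb)
        bins = np.concatenate([s.bins for s in chunk])
        levels = np.concatenate([s.levels for s in chunk])
        counts = np.array([s.bins.size for s in chunk])
        rows = np.repeat(np.arange(len(chunk)), counts)
        bound = cb.id_hvs[bins] ^ cb.level_hvs[levels - 1]
        votes = np.zeros((len(chunk), cb.dim), dtype=np.int64)
        np.add.at(votes, rows, bound)
        bits = _majority(votes, counts[:, None], cb.tie_hv)
        packed = _pack_rows(bits)
        out.extend(PackedHV(words=packed[i].copy(), dim=cb.dim) for i in range(len(chunk)))
    return out


def save_codebook(cb: Codebook, path: str | Path) -> None:
    """Dump a codebook (packed words + generation parameters) to an .npz file."""
    np.savez_compressed(
        path,
        dim=cb.dim,
        seed=cb.seed,
        flip_id=cb.flip_id,
        flip_level=cb.flip_level,
        id_words=_pack_rows(cb.id_hvs),
        level_words=_pack_rows(cb.level_hvs),
        tie_words=pack_bits(cb.tie_hv).words,
    )


def load_codebook(path: str | Path) -> Codebook:
    with np.load(path) as data:
        dim = int(data["dim"])

        def rows(words: np.ndarray) -> np.ndarray:
            return np.vstack(
                [unpack_bits(PackedHV(words=w, dim=dim)) for w in words]
            )

        id_hvs = rows(data["id_words"])
        level_hvs = rows(data["level_words"])
        tie_hv = unpack_bits(PackedHV(words=data["tie_words"], dim=dim))
        return Codebook(
            dim=dim,
            n_ids=id_hvs.shape[0],
            n_levels=level_hvs.shape[0],
            id_hvs=id_hvs,
            level_hvs=level_hvs,
            tie_hv=tie_hv,
            seed=int(data["seed"]),
            flip_id=int(data["flip_id"]),
            flip_level=int(data["flip_level"]),
        )
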