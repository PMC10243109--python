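"""Spectrum filtering, normalization and sparse quantization.

A spectrum survives preprocessing when, after removing precursor-related
peaks, out-of-range peaks and peaks below 1% of the base peak, it still
has at least 5 peaks spanning at least 250 Da. The top 50 peaks by
intensity are kept and intensities are L2-normalized. Surviving spectra
are then mapped to sparse (m/z-bin, intensity-level) pairs for
hypervector encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .io import RawSpectrum

REASON_TOO_FEW_PEAKS = "too_few_peaks"
REASON_NARROW_MZ_RANGE = "narrow_mz_range"


@dataclass(frozen=True)
class PreprocessParams:
    """Filter and quantization settings.

    ``n_bins`` (the maximum peak index range ``f``) is derived from the
    fragment m/z window and the bin width, never set directly.
    """

    min_peaks: int = 5
    min_mz_range: float = 250.0
    max_peaks_kept: int = 50
    min_intensity_frac: float = 0.01
    precursor_removal_tol: float = 1.5
    min_mz: float = 101.0
    max_mz: float = 1500.0
    bin_size: float = 0.05
    q_levels: int = 16

    def __post_init__(self) -> None:
        if not self.min_mz < self.max_mz:
            raise ValueError("min_mz must be < max_mz")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.q_levels < 2:
            raise ValueError("q_levels must be >= 2")

    @property
    def n_bins(self) -> int:
        """Number of m/z bins f = ceil((max_mz - min_mz) / bin_size)."""
        # round guard: (max-min)/bin may land epsilon above an integer
        return math.ceil(round((self.max_mz - self.min_mz) / self.bin_size, 6))


@dataclass(frozen=True)
class Rejection:
    """Tagged preprocessing failure; ``reason`` names the first failing rule."""

    identifier: str
    reason: str


@dataclass
class QuantizedSpectrum:
    """Sparse (m/z-bin, intensity-level) pairs ready for HD encoding.

    ``bins`` are strictly increasing indices in ``[0, f)``; ``levels``
    are quantization levels in ``[1, Q]``.
    """

    identifier: str
    precursor_mz: float
    precursor_charge: int
    bins: np.ndarray
    levels: np.ndarray


def l2_normalize(intensity: np.ndarray) -> np.ndarray:
    """Scale intensities so their Euclidean norm is 1."""
    norm = float(np.linalg.norm(intensity))
    if norm == 0:
        raise ValueError("cannot normalize an all-zero intensity vector")
    return intensity / norm


def preprocess_spectrum(
    raw: RawSpectrum, params: PreprocessParams = PreprocessParams()
) -> Union[RawSpectrum, Rejection]:
    """Apply the peak/spectrum filters in fixed order.

    Order: (1) remove precursor-window and out-of-range peaks; (2) remove
    peaks below ``min_intensity_frac`` of the surviving base peak;
    (3) reject spectra with too few peaks or a too-narrow m/z span;
    (4) keep the ``max_peaks_kept`` most intense peaks (ties keep lower
    m/z); (5) L2-normalize intensities. Rejection is a tagged result,
    not an exception.
    """
    mz = raw.peak_mz
    intensity = raw.peak_intensity

    keep = (
        (np.abs(mz - raw.precursor_mz) > params.precursor_removal_tol)
        & (mz >= params.min_mz)
        & (mz <= params.max_mz)
    )
    mz, intensity = mz[keep], intensity[keep]

    if intensity.size:
        keep = intensity >= params.min_intensity_frac * intensity.max()
        mz, intensity = mz[keep], intensity[keep]

    if mz.size < params.min_peaks:
        return Rejection(raw.identifier, REASON_TOO_FEW_PEAKS)
    if mz[-1] - mz[0] < params.min_mz_range:
        return Rejection(raw.identifier, REASON_NARROW_MZ_RANGE)

    if mz.size > params.max_peaks_kept:
        # highest intensity first; ties keep the lower m/z
        order = np.lexsort((mz, -intensity))[: params.max_peaks_kept]
        order.sort()  # back to ascending m/z
        mz, intensity = mz[order], intensity[order]

    return replace(raw, peak_mz=mz, peak_intensity=l2_normalize(intensity))


def vectorize_quantize(
    spec: RawSpectrum, params: PreprocessParams = PreprocessParams()
) -> QuantizedSpectrum:
    """Convert a preprocessed spectrum to sparse quantized form.

    Bin index ``i = floor((mz - min_mz)/bin_size)`` clamped to
    ``[0, f-1]``; level ``j = clip(ceil(intensity * Q), 1, Q)``. When two
    peaks fall into one bin the higher-intensity peak wins.
    """
    f = params.n_bins
    q = params.q_levels
    bins = np.floor((spec.peak_mz - params.min_mz) / params.bin_size).astype(np.int64)
    np.clip(bins, 0, f - 1, out=bins)
    levels = np.ceil(spec.peak_intensity * q).astype(np.int64)
    np.clip(levels, 1, q, out=levels)

    # resolve bin collisions: stable sort by (bin, -intensity), keep first per bin
    order = np.lexsort((-spec.peak_intensity, bins))
    bins_sorted = bins[order]
    uniq, first = np.unique(bins_sorted, return_index=True)
    return QuantizedSpectrum(
        identifier=spec.identifier,
        precursor_mz=spec.precursor_mz,
        precursor_charge=spec.precursor_charge,
        bins=uniq,
        levels=levels[order][first],
    )
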