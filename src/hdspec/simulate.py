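"""Synthetic labeled MGF datasets with planted cluster structure.

Each "peptide" template is a random fragment spectrum; replicates
perturb it with Gaussian m/z jitter, multiplicative log-normal intensity
noise, Bernoulli peak dropout, a few spurious peaks and a small
precursor jitter — the near-replicate structure a spectral clustering
tool is supposed to merge. The generator writes a standard MGF plus a
ground-truth identifier -> peptide TSV, so the whole pipeline and the
quality metrics can be exercised end to end without any real data.

What this emulates (and what it does not): replicates share the bucket
by default because the precursor jitter is kept far below the bucket
width of 1.0005079/charge Da; real acquisition-to-acquisition precursor
drift, chimeric spectra and realistic fragmentation chemistry are out of
scope.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

from .io import RawSpectrum

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the planted-cluster generator; defaults are the study conditions."""

    n_templates: int = 100
    replicates_per_template: int = 20
    n_peaks_min: int = 20
    n_peaks_max: int = 80
    mz_min: float = 101.0
    mz_max: float = 1500.0
    precursor_mz_min: float = 400.0
    precursor_mz_max: float = 1200.0
    charges: Tuple[int, ...] = (2, 3)
    mz_jitter_sd: float = 0.01
    intensity_noise_cv: float = 0.2
    peak_dropout_prob: float = 0.1
    spurious_min: int = 0
    spurious_max: int = 5
    precursor_jitter_sd: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.peak_dropout_prob <= 1:
            raise ValueError("peak_dropout_prob must be in [0, 1]")
        if min(self.mz_jitter_sd, self.intensity_noise_cv, self.precursor_jitter_sd) < 0:
            raise ValueError("jitter/noise settings must be >= 0")
        if self.n_peaks_min < 1 or self.n_peaks_max < self.n_peaks_min:
            raise ValueError("invalid peak count range")


def _random_peptide(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def generate_templates(
    params: FixtureParams, rng: Optional[np.random.Generator] = None
) -> List[Tuple[str, RawSpectrum]]:
    """Draw ``n_templates`` template spectra with distinct synthetic peptide labels.

    Peak m/z are uniform over the fragment window, intensities
    log-normal, precursor m/z uniform with a random charge. Deterministic
    per seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    templates: List[Tuple[str, RawSpectrum]] = []
    seen = set()
    for t in range(params.n_templates):
        peptide = _random_peptide(rng)
        while peptide in seen:
            peptide = _random_peptide(rng)
        seen.add(peptide)
        n_peaks = int(rng.integers(params.n_peaks_min, params.n_peaks_max + 1))
        mz = np.sort(rng.uniform(params.mz_min, params.mz_max, size=n_peaks))
        intensity = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
        template = RawSpectrum(
            identifier=f"template_{t:04d}",
            precursor_mz=float(rng.uniform(params.precursor_mz_min, params.precursor_mz_max)),
            precursor_charge=int(rng.choice(params.charges)),
            peak_mz=mz,
            peak_intensity=intensity,
        )
        templates.append((peptide, template))
    return templates


def _perturb(
    template: RawSpectrum, params: FixtureParams, rng: np.random.Generator
) -> Tuple[float, np.ndarray, np.ndarray]:
    keep = rng.random(template.n_peaks) >= params.peak_dropout_prob
    if not keep.any():
        keep[:] = True  # never emit an empty replicate
    mz = template.peak_mz[keep] + rng.normal(0.0, params.mz_jitter_sd, size=int(keep.sum()))
    if params.intensity_noise_cv > 0:
        sigma = np.sqrt(np.log1p(params.intensity_noise_cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=mz.size)
    else:
        factors = np.ones(mz.size)
    intensity = template.peak_intensity[keep] * factors
    n_spurious = int(rng.integers(params.spurious_min, params.spurious_max + 1))
    if n_spurious:
        mz = np.concatenate([mz, rng.uniform(params.mz_min, params.mz_max, size=n_spurious)])
        intensity = np.concatenate(
            [intensity, rng.uniform(0.01, 0.5, size=n_spurious) * template.peak_intensity.max()]
        )
    order = np.argsort(mz)
    precursor_mz = template.precursor_mz + float(rng.normal(0.0, params.precursor_jitter_sd))
    return precursor_mz, mz[order], np.abs(intensity[order])


def generate_dataset(
    templates: Sequence[Tuple[str, RawSpectrum]],
    params: FixtureParams,
    mgf_path: str | Path,
    labels_path: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Write perturbed replicates of every template as MGF + ground-truth TSV.

    Returns the number of spectra written (n_templates x replicates).
    Spectrum titles are ``spec_<template>_<replicate>`` and the label
    table maps each title to its template's peptide.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[1])
    entries = []
    label_rows = []
    for t, (peptide, template) in enumerate(templates):
        for r in range(params.replicates_per_template):
            precursor_mz, mz, intensity = _perturb(template, params, rng)
            title = f"spec_{t:04d}_{r:03d}"
            entries.append(
                {
                    "m/z array": mz,
                    "intensity array": intensity,
                    "params": {
                        "title": title,
                        "pepmass": precursor_mz,
                        "charge": template.precursor_charge,
                    },
                }
            )
            label_rows.append((title, peptide))
    _mgf.write(entries, str(mgf_path), file_mode="w")
    with Path(labels_path).open("w", encoding="utf-8") as fh:
        fh.write("identifier\tpeptide\n")
        for title, peptide in label_rows:
            fh.write(f"{title}\t{peptide}\n")
    return len(entries)
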