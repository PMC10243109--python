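import numpy as np
import pytest

from hdspec import (
    FixtureParams,
    PreprocessParams,
    QuantizedSpectrum,
    generate_codebook,
)


@pytest.fixture(scope="session")
def toy_codebook():
    """Small codebook: D=64, 32 bins, 8 levels."""
    return generate_codebook(dim=64, n_ids=32, n_levels=8, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_quantized(rng, n_ids, n_levels, n_peaks=None, identifier="q", mz=500.0, charge=2):
    """Random valid QuantizedSpectrum for a codebook of the given shape."""
    if n_peaks is None:
        n_peaks = int(rng.integers(1, min(n_ids, 50) + 1))
    bins = np.sort(rng.choice(n_ids, size=n_peaks, replace=False))
    levels = rng.integers(1, n_levels + 1, size=n_peaks)
    return QuantizedSpectrum(
        identifier=identifier,
        precursor_mz=mz,
        precursor_charge=charge,
        bins=bins.astype(np.int64),
        levels=levels.astype(np.int64),
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """20 templates x 10 replicates with default noise, written to disk."""
    from hdspec import generate_dataset, generate_templates

    tmp = tmp_path_factory.mktemp("fixture")
    params = FixtureParams(n_templates=20, replicates_per_template=10, seed=7)
    templates = generate_templates(params)
    mgf, labels = tmp / "data.mgf", tmp / "labels.tsv"
    n = generate_dataset(templates, params, mgf, labels)
    return {"params": params, "mgf": mgf, "labels": labels, "n": n, "dir": tmp}
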