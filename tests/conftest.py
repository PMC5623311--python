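import pytest

from eplink.synthetic import SynthConfig, generate


def small_config(seed: int = 0, **overrides) -> SynthConfig:
    """A fast two-chromosome configuration for unit tests."""
    params = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=4_000_000,
        n_genes=60,
        n_enhancers=30,
        base_count=40.0,
        n_noise_peaks_per_chrom=2,
        tad_size=400_000,
    )
    params.update(overrides)
    return SynthConfig(**params)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(small_config(seed=7))
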