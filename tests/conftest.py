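import numpy as np
import pandas as pd
import pytest

from coregbuf.simulate import Bundle, GeneratorConfig, generate


def small_config(seed: int = 11, **kw) -> GeneratorConfig:
    """Desk-scale study for unit tests (fast, but structurally complete)."""
    defaults = dict(
        seed=seed,
        n_chromosomes=2,
        genes_per_chromosome=120,
        chromosome_length=4_000_000,
        n_samples=40,
        domain_size_mean=300_000,
        max_contact_distance=2_000_000,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    return generate(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    """Hand-written 6-gene annotation on two chromosomes."""
    from coregbuf.core import make_annotation

    return make_annotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC", "gD", "gE", "gF"],
                "chromosome": ["chr1", "chr1", "chr1", "chr1", "chr2", "chr2"],
                "strand": ["-", "+", "+", "+", "+", "-"],
                # gA/gB: divergent, TSSs 800 bp apart (gA TSS at body_end)
                "body_start": [9_200, 10_800, 40_000, 90_000, 5_000, 20_000],
                "body_end": [10_000, 15_000, 45_000, 95_000, 9_000, 26_000],
            }
        )
    )
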