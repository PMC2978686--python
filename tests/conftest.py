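from __future__ import annotations

import numpy as np
import pytest

from domestiscan.model import Genome
from domestiscan.synth import SynthConfig, SyntheticDataset, generate_dataset

SMALL_CHROMS = (("I", 50_000), ("II", 50_000), ("III", 50_000))


def small_config(**overrides) -> SynthConfig:
    defaults = dict(
        chrom_lengths=SMALL_CHROMS,
        mu_scale=334.0,  # keeps event counts at paper magnitude on 150 kb
        n_genes=12,
        seed=1,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory) -> SyntheticDataset:
    """Small noiseless synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("synth_noiseless")
    return generate_dataset(small_config(), outdir)


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return Genome(
        {
            "chr1": "".join(bases[rng.integers(0, 4, size=3000)]),
            "chr2": "".join(bases[rng.integers(0, 4, size=3000)]),
        }
    )
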