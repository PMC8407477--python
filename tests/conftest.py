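import numpy as np
import pytest

from strainsift.synthetic import StrainGenome, generate_strain_panel


@pytest.fixture(scope="session")
def small_panel():
    """Three related 2 kb focal strains at 2% per-site divergence."""
    return generate_strain_panel(2000, 3, 0.02, seed=11)


@pytest.fixture(scope="session")
def background_panel():
    """Two unrelated 2 kb background genomes."""
    return [
        generate_strain_panel(2000, 1, 0.0, seed=101 + i, id_prefix=f"bg{i}_",
                              is_focal=False)[0]
        for i in range(2)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_genome(length, seed, gid="g0", is_focal=True):
    r = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in r.integers(0, 4, size=length))
    return StrainGenome(id=gid, sequence=seq, is_focal=is_focal)
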