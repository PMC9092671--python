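from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def trait_dir(tmp_path: Path) -> Path:
    """Small batch of generated trait files with a planted pairwise overlap."""
    from tacgvar.fixtures import gen_trait_files

    d = tmp_path / "traits"
    gen_trait_files(
        d, n_traits=4, n_variants=40, seed=11,
        overlap_spec={("Trait01", "Trait02"): 3},
    )
    return d


@pytest.fixture
def motif_dir(tmp_path: Path) -> Path:
    """Generated 3'UTR motif fixture with planted inside/outside variants."""
    from tacgvar.fixtures import gen_utr_motif_fixture

    d = tmp_path / "motifs"
    gen_utr_motif_fixture(d, n_genes=6, n_variants_in=4, n_variants_out=8, seed=7)
    return d
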