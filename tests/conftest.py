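import numpy as np
import pytest

from famdiv import profiles, synthio
from famdiv.seqio import MultipleAlignment, ProteinRecord


def hlh_seed_alignment(n_rows: int = 3) -> MultipleAlignment:
    """Seed alignment of identical consensus copies — a sharp, simple model."""
    return MultipleAlignment(
        [(f"seed{i}", synthio.DEFAULT_DOMAIN_CONSENSUS) for i in range(n_rows)]
    )


@pytest.fixture(scope="session")
def calibrated_model() -> profiles.ProfileModel:
    model = profiles.build_profile(hlh_seed_alignment(), model_id="HLH")
    return profiles.calibrate_evalue(model, n_shuffled=200, target_length=300, seed=17)


@pytest.fixture(scope="session")
def planted_proteome():
    """50-protein synthetic proteome: 20 planted domains, 2 truncated."""
    records, truth = synthio.generate_proteome(
        n_proteins=50, n_with_domain=20, truncation_fraction=0.1, seed=7
    )
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_background_protein(rng, length: int, pid: str = "bg") -> ProteinRecord:
    residues = "".join(
        profiles.AMINO_ACIDS[c]
        for c in rng.choice(20, size=length, p=profiles.DEFAULT_BACKGROUND)
    )
    return ProteinRecord(id=pid, residues=residues)
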