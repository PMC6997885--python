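import numpy as np
import pytest

from memlipid.simulate import (
    GuvConfig,
    LipidomeConfig,
    ProteomeConfig,
    gen_guv_contours,
    gen_lipidome,
    gen_ortholog_proteomes,
)

# Independent atomic-mass oracle: IUPAC monoisotopic masses typed by hand,
# deliberately separate from the package's mass table.
IUPAC_MONOISOTOPIC = {
    "H": 1.00782503207,
    "H[2]": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
}


def oracle_mass(composition) -> float:
    """Brute-force atomic summation against the hand-typed table."""
    return sum(IUPAC_MONOISOTOPIC[el] * n for el, n in composition.items())


@pytest.fixture(scope="session")
def noiseless_lipidome():
    return gen_lipidome(LipidomeConfig(seed=11))


@pytest.fixture(scope="session")
def small_contours():
    return gen_guv_contours(GuvConfig(kappa=20.0, sigma_bar=10.0, n_frames=800, seed=7))


@pytest.fixture(scope="session")
def proteome_cohort():
    return gen_ortholog_proteomes(
        ProteomeConfig(n_groups=120, length_shift={"japonicus": -4}, seed=13)
    )
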