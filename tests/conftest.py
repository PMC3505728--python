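import numpy as np
import pytest

from mirfate import MatureMiRNA, SimulationConfig, generate_truth


@pytest.fixture(scope="session")
def mir181b() -> MatureMiRNA:
    return MatureMiRNA("hsa-miR-181b-5p", "AACAUUCAUUGCUGUCGGUGGGU")


@pytest.fixture(scope="session")
def mir107() -> MatureMiRNA:
    return MatureMiRNA("hsa-miR-107", "AGCAGCAUUGUACAGGGCUAUCA")


@pytest.fixture()
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=120,
        n_cell_types=2,
        frac_predicted_targets=0.25,
        tf_regulon_size=10,
        rng_seed=7,
    )


@pytest.fixture()
def small_truth(small_config):
    return generate_truth(small_config)


def brute_force_scan(seq: str, patterns: dict) -> list:
    """Independent oracle: naive all-substring comparison with the same
    published precedence rules (8mer beats its embedded 7mers in place)."""
    seq = seq.upper().replace("U", "T")
    p8, p7m8, p71a = patterns["8mer"], patterns["7mer-m8"], patterns["7mer-1A"]
    found = []
    for i in range(len(seq)):
        window8 = seq[i:i + 8]
        window7 = seq[i:i + 7]
        if window8 == p8:
            found.append(("8mer", i, i + 8))
        elif window7 == p7m8:
            found.append(("7mer-m8", i, i + 7))
        elif window7 == p71a:
            if i == 0 or seq[i - 1:i + 7] != p8:
                found.append(("7mer-1A", i, i + 7))
    return found


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
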