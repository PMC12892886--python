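import numpy as np
import pytest

from restoromics.core_io import ConstructSequence
from restoromics.synthetic_data import SimulationConfig, simulate_study


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


_SUBSTITUTE = str.maketrans("ACDEFGHIKLMNPQRSTVWY", "CDEFGHIKLMNQPRSTVWYA")


def make_deletion_constructs(rng: np.random.Generator, parent_len: int = 400):
    """An endogenous full-length parent plus a diverged transgenic full-length
    copy and its midi / micro internal-deletion mutants (the human-construct
    vs mouse-gene situation: transgenics share peptides the endogenous
    protein lacks)."""
    endo = random_protein(rng, parent_len)
    # transgenic parent: substitute every 20th residue so some tryptic
    # peptides are transgenic-specific while most are shared
    tg = list(endo)
    for i in range(10, parent_len, 20):
        tg[i] = endo[i].translate(_SUBSTITUTE)
    tg = "".join(tg)
    third = parent_len // 3
    midi = tg[:third] + tg[2 * third :]  # one internal deletion
    micro = tg[: third // 3] + tg[2 * third + third // 2 :]  # larger deletion
    return [
        ConstructSequence("endoFull", endo, "endogenous", "full"),
        ConstructSequence("tgFull", tg, "transgenic", "full"),
        ConstructSequence("tgMidi", midi, "transgenic", "midi"),
        ConstructSequence("tgMicro", micro, "transgenic", "micro"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def construct_set(rng):
    return make_deletion_constructs(rng)


@pytest.fixture
def clean_cfg():
    """Noise-free, artifact-free layout for exactness checks."""
    return SimulationConfig(
        n_proteins=50,
        frac_up=0.2,
        frac_down=0.1,
        effect_log2=2.0,
        noise_cv=0.0,
        plex_shift_log2=0.0,
        coisolation_rho=0.0,
        outlier_rate=0.0,
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture
def clean_study(clean_cfg):
    return simulate_study(clean_cfg)


@pytest.fixture
def noisy_study():
    cfg = SimulationConfig(
        n_proteins=300,
        frac_up=0.1,
        frac_down=0.05,
        effect_log2=2.0,
        noise_cv=0.15,
        plex_shift_log2=0.5,
        coisolation_rho=0.02,
        outlier_rate=0.005,
        missing_rate=0.005,
        seed=11,
    )
    return simulate_study(cfg)
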