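import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from pepqc import binding, synthetic_data as sd


@pytest.fixture(scope="session")
def motifs():
    return sd.builtin_motifs()


@pytest.fixture(scope="session")
def mock_spec(motifs):
    """Small-background mock predictor spec shared across tests."""
    return binding.PredictorSpec(
        pssms={name: m.pssm for name, m in motifs.items()},
        background_size=1000,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_motif_peptides(motifs):
    """9-mer mixture of the two builtin motifs with ground-truth labels."""
    a = sd.sample_binders(motifs["SYN-A"], 60, seed=101, length_distribution={9: 1.0})
    b = sd.sample_binders(motifs["SYN-B"], 60, seed=202, length_distribution={9: 1.0})
    truth = {p: "SYN-A" for p in a}
    truth.update({p: "SYN-B" for p in b})
    return set(a) | set(b), truth


def random_peptides(rng: np.random.Generator, n: int, lengths) -> list[str]:
    from pepqc.peptide_io import CANONICAL_AA

    out = []
    for _ in range(n):
        ln = rng.choice(lengths)
        out.append("".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=ln)))
    return out
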