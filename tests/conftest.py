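import numpy as np
import pytest

import acpfuse as af


@pytest.fixture
def tiny_dataset():
    """Six hand-written peptides, three per class."""
    pos = [
        af.PeptideRecord("p1", "KLAKLAKKLAKLAK", 1),
        af.PeptideRecord("p2", "FAKKLAKLWKKLAK", 1),
        af.PeptideRecord("p3", "KWKLFKKIGAVLKV", 1),
    ]
    neg = [
        af.PeptideRecord("n1", "DENQSSDEQNSDES", 0),
        af.PeptideRecord("n2", "SSDDEEQQNNSSDE", 0),
        af.PeptideRecord("n3", "QNDESQNDESQNDE", 0),
    ]
    return af.LabelledDataset(pos + neg, provenance="hand-written fixture")


@pytest.fixture(scope="session")
def separable_dataset():
    """Small strongly separable synthetic dataset (compositional + motif bias)."""
    return af.generate(
        af.GeneratorConfig(n_pos=60, n_neg=60, effect_size=3.0, motif="KLAK", seed=7)
    )


@pytest.fixture
def fast_config():
    """Defaults scaled for quick unit-test training runs."""
    return af.ModelConfig(epochs=15, patience=5, seed=11)


@pytest.fixture
def random_peptides():
    """Seeded alphabet-clean random peptides, lengths 7-60."""
    rng = np.random.default_rng(42)
    letters = np.array(list(af.AMINO_ACIDS))
    return [
        "".join(letters[rng.integers(0, 20, size=rng.integers(7, 61))])
        for _ in range(50)
    ]
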