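import numpy as np
import pytest

from m6aloco.io import Dataset, SequenceRecord
from m6aloco.synthetic import SynthConfig, generate


def random_dataset(
    n: int = 30,
    L: int = 41,
    chromosomes=("chr1", "chr2", "chr3"),
    seed: int = 0,
    pos_fraction: float = 0.5,
) -> Dataset:
    """Uniform-background dataset with random labels and chromosomes."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n):
        seq = "".join(rng.choice(bases, size=L))
        records.append(
            SequenceRecord(
                id=f"r{i}",
                chromosome=str(rng.choice(chromosomes)),
                sequence=seq,
                label=int(rng.random() < pos_fraction),
            )
        )
    return Dataset(records, L)


@pytest.fixture
def small_dataset():
    return random_dataset(n=30, L=41, seed=11)


@pytest.fixture
def motif_dataset():
    """Fully motif-separable fixture: GGACT at the center of every positive,
    never inserted in negatives."""
    cfg = SynthConfig(
        n_pos=60,
        n_neg=60,
        L=61,
        chromosomes=("chr1", "chr2", "chr3", "chr4"),
        motif="GGACT",
        motif_insert_prob_pos=1.0,
        motif_insert_prob_neg=0.0,
        center_jitter=2,
        seed=5,
    )
    return generate(cfg)
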