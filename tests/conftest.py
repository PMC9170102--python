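import numpy as np
import pytest

from silkmotif import synthetic_data as sd


@pytest.fixture
def grammar():
    return sd.SpidroinGrammar()


@pytest.fixture
def reference_library():
    return sd.default_reference_library()


@pytest.fixture
def small_dataset(grammar):
    """Twelve synthetic spidroins with planted ground truth."""
    records, truths = [], {}
    for g in range(12):
        record, truth = sd.generate_spidroin(grammar, seed=1000 + g, gene_id=f"syn_g{g:02d}")
        records.append(record)
        truths[record.gene_id] = truth
    return records, truths


def random_core(rng: np.random.Generator, length: int, alphabet: str = "GPAS") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
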