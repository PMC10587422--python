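import numpy as np
import pytest

from circseg.dataprep import LabeledWindow, extract_positive_window
from circseg.synthdata import MotifModel, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """120 positive windows of length 101 from a planted-motif simulation."""
    cfg = SynthConfig(n_sequences=120, seed=7)
    seqs, ivs, truth = generate_dataset(cfg)
    windows = [extract_positive_window(s, iv, 50) for s, iv in zip(seqs, ivs)]
    return cfg, windows, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_window(seq: str, labels=None, provenance="positive", seq_id="w") -> LabeledWindow:
    if labels is None:
        labels = np.zeros(len(seq), dtype=np.int8)
        labels[len(seq) // 2] = 1
    return LabeledWindow(seq_id=seq_id, sequence=seq, labels=np.asarray(labels),
                         provenance=provenance)
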