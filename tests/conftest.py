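import numpy as np
import pytest

from midrp import sequence_io, simulate, transformer


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny Markov corpus: (sequences, vocab, generator truth)."""
    cfg = simulate.SequenceSimConfig(
        seed=11, n_samples=60, n_codes=6, min_len=3, max_len=8
    )
    events_df, truth = simulate.simulate_event_sequences(cfg)
    events = [
        sequence_io.MedicalEvent(
            sample_id=r.sample_id,
            code=sequence_io.truncate_code(r.icd10),
            time=r.admission_time / 30.0,
        )
        for r in events_df.itertuples()
    ]
    result = sequence_io.assemble_sequences(events)
    vocab = sequence_io.EventVocabulary(
        c for seq in result.sequences for c in seq.codes
    )
    return result.sequences, vocab, truth


@pytest.fixture(scope="session")
def tiny_state(small_corpus):
    """Random-init transformer over the tiny corpus vocabulary."""
    _, vocab, _ = small_corpus
    config = transformer.ModelConfig(
        vocab_size=vocab.n_ids,
        n_layers=2,
        n_heads=2,
        d_model=12,
        d_qk=8,
        d_ff=16,
        max_len=8,
        seed=3,
    )
    return transformer.init_state(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
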