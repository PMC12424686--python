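import pytest

import ablmkit as ak
from ablmkit.mlm import TrainSchedule


@pytest.fixture(scope="session")
def library():
    return ak.build_toy_library(seed=1)


@pytest.fixture(scope="session")
def repertoire(library):
    cfg = ak.RepertoireConfig(n_donors=5, pairs_per_donor=40, seed=11)
    return ak.generate_repertoire(cfg, library)


@pytest.fixture(scope="session")
def tokenized(repertoire):
    return [
        ak.tokenize_pair(p.heavy_aa, p.light_aa, p.pair_id, p.donor_id)
        for p in repertoire
    ]


@pytest.fixture(scope="session")
def tiny_config():
    return ak.ModelConfig(n_layers=2, d_model=32, n_heads=2, ffn_dim=64)


@pytest.fixture(scope="session")
def trained_model(tiny_config, tokenized):
    """A briefly trained miniature MLM shared by evaluation tests."""
    schedule = TrainSchedule(
        total_steps=600, warmup_steps=60, peak_lr=2e-3, batch_size=16,
        seed=42, eval_every=200,
    )
    model, trajectory, _ = ak.train_mlm(tiny_config, schedule, tokenized[20:], tokenized[:20])
    return model, trajectory


@pytest.fixture()
def untrained_model():
    return ak.TinyTransformerLM(
        ak.ModelConfig(n_layers=1, d_model=16, n_heads=2, ffn_dim=32), seed=0
    )
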