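import numpy as np
import pytest

import sigpile as sp


@pytest.fixture(scope="session")
def small_model():
    """Complete 4-mer model with MSB at position 2, mild minor effects."""
    return sp.make_synthetic_model(k=4, msb=2, seed=42)


@pytest.fixture(scope="session")
def pure_model():
    """Level is a pure function of the base at position 2."""
    return sp.make_synthetic_model(k=4, msb=2, minor_weight=0.0,
                                   level_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def dataset(small_model):
    """Small clean dataset: 300 bp reference at ~8x depth, both strands."""
    params = sp.SimParams(depth=8, seed=101, min_read_length=80)
    return sp.simulate_dataset(300, small_model, params)


def random_ss_ops(rng: np.random.Generator, max_ops: int = 30):
    """A random canonical op list (no adjacent SIG_INS/BASE_DEL runs)."""
    kinds = [sp.OpKind.MATCH, sp.OpKind.SIG_INS, sp.OpKind.BASE_DEL]
    ops = []
    prev = None
    for _ in range(int(rng.integers(0, max_ops + 1))):
        choices = [k for k in kinds if not (k is prev and k is not sp.OpKind.MATCH)]
        kind = choices[int(rng.integers(0, len(choices)))]
        ops.append(sp.SsOp(kind, int(rng.integers(1, 50))))
        prev = kind
    return ops
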