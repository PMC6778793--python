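import numpy as np
import pandas as pd
import pytest

from qtgrank import FixtureSpec, generate_fixture
from qtgrank.simulate import BinaryEffect, CountEffect


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by I/O, genome and feature tests."""
    spec = FixtureSpec(
        n_genes=400, n_chromosomes=2, n_causal=8, qtl_width_genes=20, seed=11
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def null_spec():
    """Fixture spec with every planted effect switched off."""
    effects = {}
    for name, eff in FixtureSpec().feature_effects.items():
        if isinstance(eff, BinaryEffect):
            effects[name] = BinaryEffect(eff.background_freq, 1.0, source=eff.source)
        else:
            effects[name] = CountEffect(eff.background_mean, 0.0, source=eff.source)
    return FixtureSpec(feature_effects=effects, seed=5)


def random_feature_frame(rng: np.random.Generator, n_genes=30, n_binary=3, n_numeric=3):
    """A random mixed binary/numeric feature DataFrame indexed by gene id."""
    index = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id")
    data = {}
    for j in range(n_binary):
        data[f"bin{j}"] = rng.integers(0, 2, n_genes).astype(float)
    for j in range(n_numeric):
        data[f"num{j}"] = np.round(rng.gamma(2.0, 1.5, n_genes), 6)
    return pd.DataFrame(data, index=index)
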