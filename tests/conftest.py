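import pytest

import molungn as m


@pytest.fixture(scope="session")
def tiny_spec():
    """Small but non-trivial three-view dataset spec for structural tests."""
    return m.SyntheticSpec(
        n=60, C=3,
        views=(m.ViewSpec("mRNA", "expression", p=40, s=5),
               m.ViewSpec("miRNA", "mirna", p=30, s=5),
               m.ViewSpec("meth", "methylation", p=30, s=5)),
        effect=3.0, noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    views, labels, truth = m.generate(tiny_spec)
    return views, labels, truth


@pytest.fixture(scope="session")
def fast_cfg():
    """Config scaled down for unit tests (not the published defaults)."""
    return m.RunConfig(num_epochs=30, num_heads=4, hidden_dims=8,
                       fc_dims=(32, 16), vcdn_features=32, avg_degree=5,
                       num_repeats=2)


@pytest.fixture(scope="session")
def fitted_tiny(tiny_data, fast_cfg):
    """One fitted model on the tiny dataset, shared across tests."""
    views, labels, _ = tiny_data
    model = m.MultiOmicsGAT(views, labels, fast_cfg)
    train_ids, _ = m.split(labels, 0.7, seed=5)
    return model.fit(train_ids=train_ids, seed=5)
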