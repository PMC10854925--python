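"""Shared fixtures: small synthetic panels and fast ensemble configs."""

import pytest

from alscreen import EnsembleConfig, PanelSpec, generate_panel


@pytest.fixture(scope="session")
def tiny_panel():
    """3 drugs x 100 cell lines x 20 genes with a strong planted signal."""
    spec = PanelSpec(n_drugs=3, n_cell_lines=100, n_genes=20,
                     signal_genes_per_drug=5, noise_sd=0.05,
                     target_hit_fraction=0.3, seed=42)
    return generate_panel(spec)


@pytest.fixture(scope="session")
def tiny_screen(tiny_panel):
    return tiny_panel.screens[0]


@pytest.fixture
def knn_ens():
    """Fast local-learner ensemble for loop-level tests."""
    return EnsembleConfig(backend="knn", n_members=3)


@pytest.fixture
def ridge_ens():
    return EnsembleConfig(backend="ridge", n_members=3)


@pytest.fixture
def gbm_ens_small():
    """Boosted-tree backend scaled down for unit tests."""
    return EnsembleConfig(backend="lightgbm", n_members=2, max_rounds=20,
                          patience=5, min_data_in_leaf=5)
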