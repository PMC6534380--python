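import numpy as np
import pandas as pd
import pytest

from shscreen import (
    SimConfig,
    fold_change_vs_baseline,
    log2_cpm,
    simulate_annotations,
    simulate_genome_toy,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A small seeded screen with known effects, shared across tests."""
    cfg = SimConfig(n_genes=40, n_loci=10, hairpins_per_gene=(6, 6), seed=7)
    counts, library, truth = simulate_screen(cfg)
    return cfg, counts, library, truth


@pytest.fixture(scope="session")
def small_fc(small_screen):
    cfg, counts, library, truth = small_screen
    norm = log2_cpm(counts)
    return fold_change_vs_baseline(norm, counts.samples, 4, library=library)


@pytest.fixture(scope="session")
def toy_panel():
    return simulate_genome_toy(6, genes_per_locus=4, seed=11)


@pytest.fixture(scope="session")
def annotations(small_screen):
    _, _, _, truth = small_screen
    return simulate_annotations(truth, n_stages=5, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_counts_frame(values, hairpins=None, reps=("rep1",), days=(4, 6)):
    """Tiny CountMatrix-shaped frame builder for hand examples."""
    values = np.asarray(values)
    if hairpins is None:
        hairpins = [f"h{i}" for i in range(values.shape[0])]
    cols = [f"{r}_d{d}" for r in reps for d in days]
    return pd.DataFrame(values, index=pd.Index(hairpins, name="hairpin"),
                        columns=cols)
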