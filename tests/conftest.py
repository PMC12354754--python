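import numpy as np
import pandas as pd
import pytest

from hervmap import annotation
from hervmap.simulate import SimConfig, simulate_annotation


@pytest.fixture(scope="session")
def small_sim():
    """A 10-gene / 40-HERV annotation with 10 planted exon-overlappers."""
    cfg = SimConfig(
        seed=42,
        n_genes=10,
        n_hervs=40,
        exon_overlap_fraction=0.25,
        n_cells_per_type={"CD4-T": 60, "B": 40},
        n_individuals=30,
        mean_umis_per_cell=120.0,
    )
    genes, hervs, truth = simulate_annotation(cfg)
    return cfg, genes, hervs, truth


@pytest.fixture(scope="session")
def annotated(small_sim):
    cfg, genes, hervs, truth = small_sim
    return annotation.build_annotation(hervs, genes), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_read_table(rng, n_reads=500, n_features=8, n_cells=5, ambig_fraction=0.2):
    feats = [f"F{i}" for i in range(n_features)]
    rows = []
    for i in range(n_reads):
        primary = feats[rng.integers(n_features)]
        if rng.random() < ambig_fraction:
            partner = feats[(feats.index(primary) + 1 + rng.integers(n_features - 1)) % n_features]
            cand = (primary, partner)
        else:
            cand = (primary,)
        rows.append(
            {
                "read_id": f"r{i}",
                "cell_barcode": f"C{rng.integers(n_cells)}",
                "umi": f"u{rng.integers(200):04d}",
                "feature_ids": cand,
            }
        )
    return pd.DataFrame(rows)
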