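"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from tmecompare import qc, syndata


@pytest.fixture(scope="session")
def small_cfg() -> syndata.SimConfig:
    """Compact study: 3 samples/group, 120 cells/sample, 300 genes, 3 clusters."""
    return syndata.SimConfig(
        n_samples_per_group=3,
        n_cells_per_sample=120,
        n_genes=300,
        n_clusters=3,
        markers_per_cluster=10,
        marker_logfc=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return syndata.simulate_counts(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    adata, truth = small_sim
    return qc.normalize(adata), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def gaussian_samples():
    """Cells in 10-D feature space, 5 samples with distinct planted spreads."""
    rng = np.random.default_rng(7)
    sds = [0.5, 1.0, 1.5, 2.0, 3.0]
    rows, idx, ann = [], [], []
    for s, sd in enumerate(sds):
        pts = rng.normal(scale=sd, size=(200, 10)) + rng.normal(scale=2.0, size=10)
        rows.append(pts)
        for i in range(200):
            idx.append(f"S{s}_c{i}")
            ann.append((f"S{s}", "PT" if s < 3 else "BM"))
    features = pd.DataFrame(
        np.vstack(rows), index=idx, columns=[f"PC{j + 1}" for j in range(10)]
    )
    annotation = pd.DataFrame(ann, index=idx, columns=["sample", "group"])
    return features, annotation, dict(zip([f"S{s}" for s in range(5)], sds))
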