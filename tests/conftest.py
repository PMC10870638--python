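import numpy as np
import pytest

from symclust import (
    CLUSTER_LABELS,
    clusters_from_loading_frame,
    default_catalog,
    reference_loadings,
)
from symclust.dataset import SymptomDataset


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def toy_dataset(catalog):
    """Four patients, complete data: everything present with fixed ratings."""
    n, p = 4, len(catalog)
    occ = np.ones((n, p))
    sev = np.full((n, p), 2.0)
    dis = np.full((n, p), 1.0)
    ages = np.array([45.0, 59.9, 60.0, 72.5])
    pids = [f"t{i}" for i in range(n)]
    return SymptomDataset(catalog, pids, ages, occ, sev, dis, provenance="toy")


def make_dataset(catalog, occurrence, ages=None):
    """Build a dataset from an occurrence matrix alone (no ratings)."""
    occ = np.asarray(occurrence, dtype=float)
    n = occ.shape[0]
    sev = np.full_like(occ, np.nan)
    dis = np.full_like(occ, np.nan)
    if ages is None:
        ages = np.full(n, 50.0)
    return SymptomDataset(catalog, [f"m{i}" for i in range(n)], ages, occ, sev, dis)


@pytest.fixture(scope="session")
def reference_cluster_sets():
    """Cluster sets extracted from the bundled younger/older loading tables."""
    sets = {}
    for group in ("younger", "older"):
        sets[group] = clusters_from_loading_frame(
            reference_loadings(group), group=group, labels=CLUSTER_LABELS
        )
    return sets
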