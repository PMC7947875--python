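"""Shared fixtures: small hand-built toys and the default synthetic dataset.

The default synthetic dataset (2 macrochromosomes of 80 Mb, 6 micros of
10–20 Mb, 1 Mb bins, 2e6 sampled contacts, seed 1) is generated once per
session; recovery-style tests all read from it.
"""

import numpy as np
import pytest

from microhic import balance
from microhic import compartment_calling as cc
from microhic import embedding_3d as e3
from microhic import synthetic_nucleus as syn
from microhic.contact_io import BinnedGenome, ChromSizes, ContactMap, bin_genome


@pytest.fixture(scope="session")
def toy3_genome() -> BinnedGenome:
    """Three chromosomes (100, 100, 50 Mb) at 50 Mb bins; chrC is micro."""
    sizes = ChromSizes(("chrA", "chrB", "chrC"), (100_000_000, 100_000_000, 50_000_000))
    return bin_genome(sizes, bin_size=50_000_000, micro_threshold_bp=60_000_000)


@pytest.fixture(scope="session")
def toy3_cmap(toy3_genome) -> ContactMap:
    """Pairwise chromosome trans sums: AB = 100, AC = 150, BC = 150."""
    # bins: chrA {0,1}, chrB {2,3}, chrC {4}
    entries = [(0, 2, 60.0), (1, 3, 40.0), (0, 4, 150.0), (2, 4, 90.0), (3, 4, 60.0)]
    i, j, v = zip(*entries)
    return ContactMap.from_entries(toy3_genome, i, j, v)


@pytest.fixture(scope="session")
def default_dataset() -> syn.SyntheticDataset:
    return syn.generate_dataset(syn.default_params())


@pytest.fixture(scope="session")
def balanced_default(default_dataset) -> ContactMap:
    return balance(default_dataset.cmap)


@pytest.fixture(scope="session")
def default_track(balanced_default, default_dataset) -> cc.CompartmentTrack:
    return cc.call_compartments(balanced_default, default_dataset.gc)


@pytest.fixture(scope="session")
def default_embedding(balanced_default) -> e3.Embedding3D:
    return e3.embed_contacts(balanced_default, seed=0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
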