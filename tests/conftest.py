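import numpy as np
import pandas as pd
import pytest

from psibound.geno_io import GenotypeDataset


def make_dataset(dosages, pops, coords=None, positions=None, lonlat=False):
    """GenotypeDataset from a sites x individuals array and per-column pops."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_sites, n_ind = dosages.shape
    individuals = [f"i{k}" for k in range(n_ind)]
    pop_of = dict(zip(individuals, pops))
    unique = list(dict.fromkeys(pops))
    if coords is None:
        coords = {p: (float(k), 0.0) for k, p in enumerate(unique)}
    coord_df = pd.DataFrame(
        {p: {"x": xy[0], "y": xy[1]} for p, xy in coords.items()}
    ).T
    return GenotypeDataset(
        dosages=dosages,
        site_ids=np.array([f"s{k}" for k in range(n_sites)], dtype=object),
        positions=None if positions is None else np.asarray(positions, float),
        individuals=np.array(individuals, dtype=object),
        pop_of=pop_of,
        coords=coord_df,
        lonlat=lonlat,
    )


@pytest.fixture
def two_pop_hand_dataset():
    """One diploid per population; projection to 2 copies is the identity.

    Genotype pairs (A, B) per site: (2,1), (2,1), (1,2), (0,1), (1,1).
    f_AB (het in A, fixed-derived in B) = 1; f_BA = 2; S = 5; psi_AB = -0.2.
    """
    dosages = np.array([
        [2, 1],
        [2, 1],
        [1, 2],
        [0, 1],
        [1, 1],
    ])
    return make_dataset(dosages, ["A", "B"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_sites=200, pops=("A", "B", "C"), n_per_pop=4,
                   missing_rate=0.0, coords=None):
    """Random segregating dataset (allele frequencies drawn per population)."""
    cols = []
    pop_list = []
    for p in pops:
        freqs = rng.uniform(0.05, 0.95, n_sites)
        g = rng.binomial(2, freqs[:, None], size=(n_sites, n_per_pop))
        cols.append(g)
        pop_list += [p] * n_per_pop
    dosages = np.concatenate(cols, axis=1).astype(np.int16)
    if missing_rate:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = -1
    return make_dataset(dosages, pop_list, coords=coords)
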