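"""Stepping-stone and panmictic meta-population simulators.

Two complementary generators share output conventions:

* :func:`run_stepping_stone` / :func:`run_panmictic` -- a forward-in-time,
  individual-based non-Wright-Fisher model: hermaphroditic diploids without
  selfing, discrete non-overlapping generations, Poisson(1.04) offspring per
  individual with a random non-self mate in the same deme, ceiling density
  regulation to the deme carrying capacity K, and per-individual migration.
  Each individual emigrates with total probability M, drawing one of the
  2 * dims lattice directions uniformly; moves off the grid are cancelled, so
  the realized per-adjacent-pair exchange rate is M / (2 * dims).  A single
  origin deme is burned in to mutation-drift equilibrium before colonization
  opens; t0 is the cycle at which the total census first reaches 98% of K * N.

* :func:`coalescent_fixture` -- an msprime stand-in for the forward model's
  equilibrium end state, using the matching migration matrix (per-pair rate
  M / (2 * dims)).  It is orders of magnitude faster and is the desk-scale
  oracle for equilibrium psi/F_ST behavior.

The reference-scale configuration (81 demes, K = 1000, 128k cycles) is expressible
but is a cluster-scale run; tests and calibration use reduced configurations.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._genome import make_gamete, collect_genotypes
from .geno_io import GenotypeDataset

__all__ = [
    "SteppingStoneConfig",
    "SimResult",
    "run_stepping_stone",
    "run_panmictic",
    "coalescent_fixture",
]

_EMPTY = np.empty(0, dtype=np.float64)


@dataclasses.dataclass
class SteppingStoneConfig:
    """Forward-model parameters (defaults follow the reference experiment).

    ``migration`` is the total per-individual emigration probability per cycle,
    split uniformly over the 2 * dims lattice directions.  ``origin`` is the
    deme index (0-based) whose population is burned in before the expansion;
    ``sample_times`` are cycles post-t0 at which genotypes are saved.
    """

    n_demes: int = 81
    K: int = 1000
    dims: int = 1
    migration: float = 0.01
    origin: int = 0
    offspring_mean: float = 1.04
    mu: float = 1.5e-7
    r: float = 1.5e-7
    L: float = 1e6
    burn_in_cycles: Optional[int] = None   # default 10 * 2K
    sample_times: Sequence[int] = (100, 200, 400, 800, 1600, 4000, 8000,
                                   16000, 32000, 64000, 128000)
    n_sample_per_deme: int = 5
    cycle_cap: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.migration <= 1):
            raise ValueError("migration must be in [0, 1]")
        if self.offspring_mean <= 1:
            raise ValueError("offspring_mean must exceed 1 for the expansion to proceed")
        if self.dims not in (1, 2):
            raise ValueError("dims must be 1 or 2")
        if self.dims == 2:
            side = int(round(self.n_demes ** 0.5))
            if side * side != self.n_demes:
                raise ValueError("2D models need a square number of demes")

    @property
    def side(self) -> int:
        return self.n_demes if self.dims == 1 else int(round(self.n_demes ** 0.5))

    def deme_coords(self) -> np.ndarray:
        if self.dims == 1:
            return np.column_stack([np.arange(self.n_demes, dtype=float),
                                    np.zeros(self.n_demes)])
        side = self.side
        rows, cols = np.divmod(np.arange(self.n_demes), side)
        return np.column_stack([cols.astype(float), rows.astype(float)])


@dataclasses.dataclass
class SimResult:
    """Simulator output: one GenotypeDataset per saved sampling time."""

    samples: dict                     # cycle (post-t0) -> GenotypeDataset
    t0_cycle: Optional[int]
    true_origin: np.ndarray
    census: list
    config: object
    seed: int
    completed: bool = True
    diagnostic: str = ""


def _neighbors(cfg: SteppingStoneConfig):
    """For each deme, the neighbor index per lattice direction (-1 off-grid)."""
    n = cfg.n_demes
    if cfg.dims == 1:
        nbr = np.full((n, 2), -1, dtype=int)
        nbr[1:, 0] = np.arange(n - 1)       # left
        nbr[:-1, 1] = np.arange(1, n)       # right
        return nbr
    side = cfg.side
    nbr = np.full((n, 4), -1, dtype=int)
    for d in range(n):
        r, c = divmod(d, side)
        if c > 0:
            nbr[d, 0] = d - 1
        if c < side - 1:
            nbr[d, 1] = d + 1
        if r > 0:
            nbr[d, 2] = d - side
        if r < side - 1:
            nbr[d, 3] = d + side
    return nbr


def _reproduce_deme(deme, cfg, rng):
    """Non-WF reproduction: Poisson offspring with random non-self mates."""
    n = len(deme)
    if n < 2:
        return []
    counts = rng.poisson(cfg.offspring_mean, n)
    offspring = []
    for i in np.flatnonzero(counts):
        for _ in range(counts[i]):
            j = rng.integers(n - 1)
            if j >= i:
                j += 1
            child = (
                make_gamete(*deme[i], cfg.L, cfg.mu, cfg.r, rng),
                make_gamete(*deme[j], cfg.L, cfg.mu, cfg.r, rng),
            )
            offspring.append(child)
    return offspring


def _regulate(deme, K, rng):
    if len(deme) <= K:
        return deme
    keep = rng.choice(len(deme), size=K, replace=False)
    return [deme[k] for k in keep]


def _migrate(demes, cfg, rng, panmictic=False):
    nbr = None if panmictic else _neighbors(cfg)
    incoming = [[] for _ in demes]
    staying = [[] for _ in demes]
    n_dir = 2 * cfg.dims
    for d, deme in enumerate(demes):
        if not deme:
            continue
        moves = rng.random(len(deme)) < cfg.migration
        for k, ind in enumerate(deme):
            if not moves[k]:
                staying[d].append(ind)
                continue
            if panmictic:
                tgt = rng.integers(len(demes) - 1)
                if tgt >= d:
                    tgt += 1
            else:
                tgt = nbr[d, rng.integers(n_dir)]
                if tgt < 0:        # off-grid move cancelled
                    staying[d].append(ind)
                    continue
            incoming[tgt].append(ind)
    return [staying[d] + incoming[d] for d in range(len(demes))]


def _sample_dataset(demes, cfg, rng) -> GenotypeDataset:
    """Five (or fewer, flagged empty) diploids per deme as a GenotypeDataset."""
    pairs = []
    pop_of = {}
    individuals = []
    coords = cfg.deme_coords()
    for d, deme in enumerate(demes):
        if not deme:
            continue
        take = min(cfg.n_sample_per_deme, len(deme))
        idx = rng.choice(len(deme), size=take, replace=False)
        for t, k in enumerate(idx):
            name = f"d{d + 1}_i{t + 1}"
            individuals.append(name)
            pop_of[name] = f"d{d + 1}"
            pairs.append(deme[k])
    positions, dos = collect_genotypes(pairs)
    coord_df = pd.DataFrame(coords, columns=["x", "y"],
                            index=[f"d{d + 1}" for d in range(cfg.n_demes)])
    return GenotypeDataset(
        dosages=dos,
        site_ids=np.array([f"s{k}" for k in range(len(positions))], dtype=object),
        positions=positions,
        individuals=np.array(individuals, dtype=object),
        pop_of=pop_of,
        coords=coord_df,
    )


def _run_forward(cfg: SteppingStoneConfig, panmictic: bool) -> SimResult:
    rng = np.random.default_rng(cfg.seed)
    demes = [[] for _ in range(cfg.n_demes)]
    demes[cfg.origin] = [(_EMPTY, _EMPTY) for _ in range(cfg.K)]

    burn_in = cfg.burn_in_cycles
    if burn_in is None:
        burn_in = 10 * 2 * cfg.K
    for _ in range(burn_in):
        deme = demes[cfg.origin]
        deme = deme + _reproduce_deme(deme, cfg, rng)
        # parents die (non-overlapping generations): offspring only
        deme = deme[len(demes[cfg.origin]):]
        demes[cfg.origin] = _regulate(deme, cfg.K, rng)
        if len(demes[cfg.origin]) < 2:
            return SimResult({}, None, cfg.deme_coords()[cfg.origin], [],
                             cfg, cfg.seed, completed=False,
                             diagnostic="origin deme lost during burn-in")

    target = 0.98 * cfg.K * cfg.n_demes
    census = []
    t0 = None
    samples = {}
    want = sorted(cfg.sample_times)
    cycle = 0
    while cycle < cfg.cycle_cap:
        cycle += 1
        new = [_reproduce_deme(d, cfg, rng) for d in demes]
        demes = [_regulate(nd, cfg.K, rng) for nd in new]
        demes = _migrate(demes, cfg, rng, panmictic=panmictic)
        total = sum(len(d) for d in demes)
        census.append(total)
        if total == 0:
            return SimResult(samples, t0, cfg.deme_coords()[cfg.origin], census,
                             cfg, cfg.seed, completed=False,
                             diagnostic="meta-population went extinct")
        if t0 is None and total >= target:
            t0 = cycle
        if t0 is not None:
            post = cycle - t0
            while want and want[0] <= post:
                tpt = want.pop(0)
                samples[tpt] = _sample_dataset(demes, cfg, rng)
            if not want:
                break
    completed = t0 is not None and not want
    diag = "" if completed else (
        "expansion not completed within cycle cap" if t0 is None
        else f"cycle cap reached before sampling times {want}")
    return SimResult(samples, t0, cfg.deme_coords()[cfg.origin], census,
                     cfg, cfg.seed, completed=completed, diagnostic=diag)


def run_stepping_stone(cfg: SteppingStoneConfig) -> SimResult:
    """Forward non-WF stepping-stone simulation (1D chain or 2D grid)."""
    if cfg.migration == 0:
        return SimResult({}, None, cfg.deme_coords()[cfg.origin], [], cfg,
                         cfg.seed, completed=False,
                         diagnostic="migration is 0: colonization cannot complete")
    return _run_forward(cfg, panmictic=False)


def run_panmictic(cfg: SteppingStoneConfig) -> SimResult:
    """As :func:`run_stepping_stone` but with all-to-all migration.

    Coordinates are still assigned on the chain/grid so origin inference can be
    evaluated against a true null.
    """
    if cfg.migration == 0:
        return SimResult({}, None, cfg.deme_coords()[cfg.origin], [], cfg,
                         cfg.seed, completed=False,
                         diagnostic="migration is 0: colonization cannot complete")
    return _run_forward(cfg, panmictic=True)


# -- coalescent equilibrium fixtures -----------------------------------------

def _deme_coords(n_demes, dims):
    if dims == 1:
        return np.column_stack([np.arange(n_demes, dtype=float), np.zeros(n_demes)])
    side = int(round(n_demes ** 0.5))
    rows, cols = np.divmod(np.arange(n_demes), side)
    return np.column_stack([cols.astype(float), rows.astype(float)])


def _to_dataset(dosages, positions, n_demes, dip_per_deme, sample_demes, dims):
    coords = _deme_coords(n_demes, dims)
    pop_of = {}
    individuals = []
    for d in sample_demes:
        for t in range(dip_per_deme):
            name = f"d{d + 1}_i{t + 1}"
            individuals.append(name)
            pop_of[name] = f"d{d + 1}"
    coord_df = pd.DataFrame(coords, columns=["x", "y"],
                            index=[f"d{k + 1}" for k in range(n_demes)])
    return GenotypeDataset(
        dosages=dosages.astype(np.int16),
        site_ids=np.array([f"s{k}" for k in range(dosages.shape[0])], dtype=object),
        positions=positions,
        individuals=np.array(individuals, dtype=object),
        pop_of=pop_of,
        coords=coord_df,
    )


def coalescent_fixture(n_demes, deme_size, m, n_snps, dims=1, seed=0,
                       dip_per_deme=5, sample_demes=None, mu=1.5e-7,
                       chunk_bp=5000, panmictic=False, sequence_length=None,
                       recombination_rate=None) -> GenotypeDataset:
    """Equilibrium coalescent sample under the forward model's migration matrix.

    ``m`` is the total per-individual migration probability of the forward
    model; the per-adjacent-pair backward rate is ``m / (2 * dims)``.  With
    ``panmictic=True`` the sample is drawn from one random-mating pool of
    ``n_demes * deme_size`` diploids and individuals are labeled into demes
    with chain/grid coordinates.

    By default, independent ``chunk_bp`` chromosomes are accumulated until
    ``n_snps`` biallelic sites are collected (unlinked-site mode; positions are
    offset per chunk and are not meaningful for LD).  Passing
    ``sequence_length`` (and optionally ``recombination_rate``) instead
    simulates one linked chromosome and returns all its sites -- the mode used
    for the adjacent-SNP LD check.
    """
    import msprime

    if min(n_demes, deme_size, dip_per_deme) <= 0 or m < 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    if sample_demes is None:
        sample_demes = list(range(n_demes))

    if panmictic:
        demography = msprime.Demography()
        demography.add_population(initial_size=n_demes * deme_size)
        samples = {0: dip_per_deme * len(sample_demes)}
    else:
        if dims == 1:
            demography = msprime.Demography.stepping_stone_model(
                [deme_size] * n_demes, migration_rate=m / 2, boundaries=True)
        else:
            side = int(round(n_demes ** 0.5))
            if side * side != n_demes:
                raise ValueError("2D fixtures need a square number of demes")
            demography = msprime.Demography()
            for _ in range(n_demes):
                demography.add_population(initial_size=deme_size)
            mm = np.zeros((n_demes, n_demes))
            rate = m / 4
            for r_ in range(side):
                for c in range(side):
                    k = r_ * side + c
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r_ + dr, c + dc
                        if 0 <= rr < side and 0 <= cc < side:
                            mm[k, rr * side + cc] = rate
            demography.migration_matrix = mm
        samples = {d: dip_per_deme for d in sample_demes}

    def _seed():
        return int(rng.integers(1, 2 ** 31 - 1))

    if sequence_length is not None:
        ts = msprime.sim_ancestry(
            samples=samples, demography=demography,
            sequence_length=sequence_length,
            recombination_rate=recombination_rate or 0.0,
            random_seed=_seed())
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=_seed(),
                                    model=msprime.BinaryMutationModel())
        G = mts.genotype_matrix()
        positions = np.array([s.position for s in mts.sites()])
        dos = G[:, 0::2] + G[:, 1::2]
        return _to_dataset(dos, positions, n_demes, dip_per_deme, sample_demes, dims)

    mats, poss = [], []
    collected = 0
    chunk_idx = 0
    reps = msprime.sim_ancestry(samples=samples, demography=demography,
                                sequence_length=chunk_bp,
                                num_replicates=1_000_000, random_seed=_seed())
    for ts in reps:
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=_seed(),
                                    model=msprime.BinaryMutationModel())
        G = mts.genotype_matrix()
        if G.shape[0]:
            mats.append(G[:, 0::2] + G[:, 1::2])
            poss.append(np.array([s.position for s in mts.sites()])
                        + chunk_idx * chunk_bp)
            collected += G.shape[0]
        chunk_idx += 1
        if collected >= n_snps:
            break
    dos = np.vstack(mats)[:n_snps]
    positions = np.concatenate(poss)[:n_snps]
    return _to_dataset(dos, positions, n_demes, dip_per_deme, sample_demes, dims)
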