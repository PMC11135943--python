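"""Continuous-space, age-structured simulator on a resistance landscape.

A hermaphroditic (no selfing), iteroparous organism with overlapping
generations moves on a grid
of habitat quality q in [0, 1] (0 = land or deep sea).  Survival each cycle is
the fitness

    f = (k * q / c) * (1 - m[age])

where ``m = [0.7, 0, 0, 0.25, 0.5, 0.75, 1.0]`` is the age-specific mortality
(ages 0..6, reproduction from age 1), ``c`` is the local competition felt by
the individual, rescaled so that c ~ k when the population is at carrying
capacity, and ``k`` scales the total population size.  Dispersal draws eight
candidate directions; each candidate distance is U(0,1) * q(source cell) *
d_max, a candidate is invalid when its straight path crosses a q = 0 cell,
leaves the map, or accumulates path resistance (sum of 1 - q over traversed
cells) above s_max = 8, and one valid candidate is chosen with weight
w = 1 - s / s_max.  An individual with no valid candidate dies (absorbing
boundaries), which keeps density proportional to habitat quality and produces
boundary effects at range margins.

Expansion modes: ``RE`` seeds only a burn-in region and lets individuals
colonize the rest of the map (a range expansion); ``DE`` re-seeds the whole
map from the burn-in population (demographic expansion without a spatial
component).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._genome import make_gamete, collect_genotypes
from .geno_io import GenotypeDataset
from .steppingstone_sim import SimResult

__all__ = [
    "ResistanceMap",
    "Agent",
    "ContinuousConfig",
    "fitness",
    "path_cells",
    "path_resistance",
    "propose_dispersal",
    "run_continuous",
]

MORTALITY = np.array([0.7, 0.0, 0.0, 0.25, 0.5, 0.75, 1.0])
MAX_AGE = 6

# expected individuals per cell at carrying capacity is k * q / CAP_SCALE;
# 25 reconciles k = 100 with a total K ~ 7e5 on the 398 x 855 reference map
CAP_SCALE = 25.0


@dataclasses.dataclass
class ResistanceMap:
    """Habitat-quality grid; resistance of a cell is 1 - q."""

    q: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        if self.q.ndim != 2:
            raise ValueError("map must be 2-dimensional")
        if (self.q < 0).any() or (self.q > 1).any():
            raise ValueError("habitat quality must lie in [0, 1]")

    @property
    def shape(self):
        return self.q.shape

    @classmethod
    def uniform(cls, rows, cols, q=0.516):
        return cls(np.full((rows, cols), q))

    @classmethod
    def from_tsv(cls, path):
        return cls(np.loadtxt(path))

    def to_tsv(self, path):
        np.savetxt(path, self.q, fmt="%.6g")

    def cell_of(self, pos):
        """(row, col) of a continuous (x, y) position; x = col, y = row."""
        return int(np.floor(pos[1])), int(np.floor(pos[0]))

    def quality_at(self, pos) -> float:
        r, c = self.cell_of(pos)
        if not (0 <= r < self.q.shape[0] and 0 <= c < self.q.shape[1]):
            return 0.0
        return float(self.q[r, c])


@dataclasses.dataclass
class Agent:
    position: np.ndarray
    age: int
    haplotypes: tuple
    alive: bool = True


@dataclasses.dataclass
class ContinuousConfig:
    """Reduced-scale defaults; the reference experiment's map is cluster-scale."""

    d_max: float = 20.0
    k: float = 10.0
    s_max: float = 8.0
    expansion: str = "RE"              # or "DE"
    burn_in_cycles: int = 300
    burn_in_fraction: float = 0.1      # leftmost columns seeded before expansion
    sample_times: Sequence[int] = (50, 100, 200)
    n_cores: int = 8
    core_sample: int = 10
    mate_radius: float = 3.0
    mu: float = 1e-8
    r: float = 1e-8
    L: float = 2.3e6
    cycle_cap: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.expansion not in ("RE", "DE"):
            raise ValueError("expansion must be RE or DE")


def fitness(q, age, c, k) -> float:
    """Survival probability f = (k q / c)(1 - m[age]), clamped to [0, 1]."""
    if c <= 0:
        c = 1e-12
    f = (k * q / c) * (1.0 - MORTALITY[age])
    return float(min(max(f, 0.0), 1.0))


def path_cells(p0, p1):
    """Supercover rasterization: every grid cell the segment touches, once."""
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    cells = []
    n_steps = max(int(np.ceil(2 * max(abs(x1 - x0), abs(y1 - y0)))), 1) * 2
    ts = np.linspace(0.0, 1.0, n_steps + 1)
    seen = set()
    for t in ts:
        x = x0 + t * (x1 - x0)
        y = y0 + t * (y1 - y0)
        cell = (int(np.floor(y)), int(np.floor(x)))
        if cell not in seen:
            seen.add(cell)
            cells.append(cell)
    return cells


def path_resistance(p0, p1, rmap: ResistanceMap):
    """Summed resistance (1 - q) over traversed cells; inf when blocked/off-map."""
    rows, cols = rmap.shape
    s = 0.0
    for r, c in path_cells(p0, p1):
        if not (0 <= r < rows and 0 <= c < cols):
            return np.inf
        q = rmap.q[r, c]
        if q == 0:
            return np.inf
        s += 1.0 - q
    return s


def propose_dispersal(position, rmap: ResistanceMap, d_max, rng, s_max=8.0,
                      n_directions=8):
    """New position for one dispersal event, or None (death).

    Candidate distance per direction is U(0,1) * q(source cell) * d_max;
    candidates whose straight path is blocked, leaves the map, or exceeds the
    resistance budget are invalid; one valid candidate is chosen with weight
    1 - s / s_max.
    """
    q_src = rmap.quality_at(position)
    if q_src == 0:
        return None
    angles = rng.uniform(0, 2 * np.pi, n_directions)
    dists = rng.uniform(0, 1, n_directions) * q_src * d_max
    candidates = []
    weights = []
    for a, d in zip(angles, dists):
        new = np.array([position[0] + d * np.cos(a), position[1] + d * np.sin(a)])
        rows, cols = rmap.shape
        if not (0 <= new[0] < cols and 0 <= new[1] < rows):
            continue
        s = path_resistance(position, new, rmap)
        if s > s_max:
            continue
        candidates.append(new)
        weights.append(1.0 - s / s_max)
    if not candidates:
        return None
    w = np.asarray(weights)
    if w.sum() <= 0:
        idx = rng.integers(len(candidates))
    else:
        idx = rng.choice(len(candidates), p=w / w.sum())
    return candidates[idx]


def _local_competition(agents, rmap: ResistanceMap, k):
    """Competition c per agent: local density over local capacity, times k.

    Density is counted on the 3 x 3 cell neighborhood; capacity of the
    neighborhood is k * sum(q) / CAP_SCALE, so c ~ k when the local census
    matches the capacity profile.
    """
    rows, cols = rmap.shape
    counts = np.zeros((rows, cols))
    cells = []
    for a in agents:
        r, c = rmap.cell_of(a.position)
        r = min(max(r, 0), rows - 1)
        c = min(max(c, 0), cols - 1)
        counts[r, c] += 1
        cells.append((r, c))
    # neighborhood sums via padded cumulative trick (3x3 box filter)
    padded = np.pad(counts, 1)
    box = sum(padded[i:i + rows, j:j + cols] for i in range(3) for j in range(3))
    qpad = np.pad(rmap.q, 1)
    qbox = sum(qpad[i:i + rows, j:j + cols] for i in range(3) for j in range(3))
    cap = np.maximum(k * qbox / CAP_SCALE, 1e-9)
    cvals = k * box / cap
    return np.array([cvals[r, c] for r, c in cells])


def _reproduce(agents, cfg, rng):
    """Poisson(1) offspring per adult, with a random non-self mate in radius.

    Hermaphroditic with no selfing; an adult with no potential mate within
    ``mate_radius`` skips reproduction this cycle.
    """
    adults = [a for a in agents if a.age >= 1]
    if len(adults) < 2:
        return []
    pos = np.array([a.position for a in adults])
    offspring = []
    for i, parent in enumerate(adults):
        d2 = ((pos - parent.position) ** 2).sum(axis=1)
        near = np.flatnonzero(d2 <= cfg.mate_radius ** 2)
        near = near[near != i]
        if near.size == 0:
            continue
        mate = adults[int(rng.choice(near))]
        for _ in range(rng.poisson(1.0)):
            child = Agent(
                position=parent.position.copy(),
                age=0,
                haplotypes=(
                    make_gamete(*parent.haplotypes, cfg.L, cfg.mu, cfg.r, rng),
                    make_gamete(*mate.haplotypes, cfg.L, cfg.mu, cfg.r, rng),
                ),
            )
            offspring.append(child)
    return offspring


def _cycle(agents, rmap, cfg, rng):
    # aging
    for a in agents:
        a.age = min(a.age + 1, MAX_AGE)
    # reproduction (adults), then viability by fitness, then dispersal
    agents = agents + _reproduce(agents, cfg, rng)
    cvals = _local_competition(agents, rmap, cfg.k)
    survivors = []
    for a, c in zip(agents, cvals):
        q = rmap.quality_at(a.position)
        if rng.random() < fitness(q, a.age, c, cfg.k):
            survivors.append(a)
    out = []
    for a in survivors:
        new = propose_dispersal(a.position, rmap, cfg.d_max, rng, s_max=cfg.s_max)
        if new is None:
            continue  # absorbing boundary: no viable move kills the individual
        a.position = new
        out.append(a)
    return out


def _select_cores(agents, n_cores, rng):
    """Core coordinates via k-means on individual positions (seeded)."""
    from scipy.cluster.vq import kmeans2

    pos = np.array([a.position for a in agents])
    n_cores = min(n_cores, len(agents))
    centers, _ = kmeans2(pos, n_cores, minit="++", seed=rng.integers(2 ** 31 - 1))
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    return centers[order]


def _sample_cores(agents, cores, core_sample):
    pos = np.array([a.position for a in agents])
    pairs, pop_of, individuals = [], {}, []
    coords_rows = {}
    taken = set()
    for ci, center in enumerate(cores):
        d2 = ((pos - center) ** 2).sum(axis=1)
        order = [i for i in np.argsort(d2) if i not in taken][:core_sample]
        taken.update(order)
        pname = f"c{ci + 1}"
        coords_rows[pname] = center
        for t, i in enumerate(order):
            name = f"{pname}_i{t + 1}"
            individuals.append(name)
            pop_of[name] = pname
            pairs.append(agents[i].haplotypes)
    positions, dos = collect_genotypes(pairs)
    coord_df = pd.DataFrame(
        {p: {"x": xy[0], "y": xy[1]} for p, xy in coords_rows.items()}
    ).T
    return GenotypeDataset(
        dosages=dos,
        site_ids=np.array([f"s{k}" for k in range(len(positions))], dtype=object),
        positions=positions,
        individuals=np.array(individuals, dtype=object),
        pop_of=pop_of,
        coords=coord_df,
    )


def run_continuous(cfg: ContinuousConfig, rmap: ResistanceMap,
                   cores: Optional[np.ndarray] = None) -> SimResult:
    """Burn in a seed region, expand (RE) or re-seed the map (DE), and sample.

    Returns a :class:`SimResult` whose samples map cycles-since-expansion-start
    to GenotypeDatasets of ``n_cores`` x ``core_sample`` individuals.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = rmap.shape
    seed_cols = max(int(np.ceil(cols * cfg.burn_in_fraction)), 1)
    seed_map = ResistanceMap(np.where(
        np.arange(cols)[None, :] < seed_cols, rmap.q, 0.0))

    # initial agents on habitable seed cells, at local capacity
    agents = []
    for r in range(rows):
        for c in range(seed_cols):
            q = rmap.q[r, c]
            n0 = rng.poisson(cfg.k * q / CAP_SCALE)
            for _ in range(n0):
                agents.append(Agent(
                    position=np.array([c + rng.random(), r + rng.random()]),
                    age=int(rng.integers(1, MAX_AGE)),
                    haplotypes=(np.empty(0), np.empty(0)),
                ))
    if len(agents) < 2:
        return SimResult({}, None, np.zeros(2), [], cfg, cfg.seed,
                         completed=False, diagnostic="seed region uninhabitable")

    census = []
    for _ in range(cfg.burn_in_cycles):
        agents = _cycle(agents, seed_map, cfg, rng)
        census.append(len(agents))
        if len(agents) < 2:
            return SimResult({}, None, np.zeros(2), census, cfg, cfg.seed,
                             completed=False, diagnostic="extinction during burn-in")

    true_origin = np.array([seed_cols / 2.0, rows / 2.0])
    if cfg.expansion == "DE":
        # demographic expansion: burn-in population immediately seeds the map
        habit = np.argwhere(rmap.q > 0)
        for a in agents:
            r, c = habit[rng.integers(len(habit))]
            a.position = np.array([c + rng.random(), r + rng.random()])

    samples = {}
    want = sorted(cfg.sample_times)
    cycle = 0
    while want and cycle < cfg.cycle_cap:
        cycle += 1
        agents = _cycle(agents, rmap, cfg, rng)
        census.append(len(agents))
        if len(agents) < 2:
            return SimResult(samples, 0, true_origin, census, cfg, cfg.seed,
                             completed=False, diagnostic="extinction after expansion start")
        while want and want[0] <= cycle:
            tpt = want.pop(0)
            core_pts = cores if cores is not None else _select_cores(
                agents, cfg.n_cores, rng)
            samples[tpt] = _sample_cores(agents, core_pts, cfg.core_sample)
    return SimResult(samples, 0, true_origin, census, cfg, cfg.seed,
                     completed=not want,
                     diagnostic="" if not want else f"cycle cap before {want}")
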