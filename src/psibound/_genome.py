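"""Minimal forward-in-time genome bookkeeping for the individual-based models.

A haplotype is a sorted float array of derived-mutation positions on a single
chromosome of length L (infinite-sites on a continuous coordinate: every new
mutation gets a fresh position, and positions collide with probability zero).
Gametes recombine with a Poisson number of crossovers at rate r per bp and
acquire Poisson(mu * L) new mutations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_gamete", "collect_genotypes"]

_EMPTY = np.empty(0, dtype=np.float64)


def make_gamete(hap1, hap2, L, mu, r, rng):
    """One recombinant gamete from a diploid parent, with new mutations."""
    n_cross = rng.poisson(r * L)
    first = rng.integers(2)
    if n_cross == 0:
        gamete = (hap1 if first == 0 else hap2).copy()
    else:
        breaks = np.sort(rng.uniform(0, L, n_cross))
        edges = np.concatenate(([0.0], breaks, [L]))
        pieces = []
        haps = (hap1, hap2) if first == 0 else (hap2, hap1)
        for k in range(len(edges) - 1):
            src = haps[k % 2]
            lo = np.searchsorted(src, edges[k], side="left")
            hi = np.searchsorted(src, edges[k + 1], side="left")
            if hi > lo:
                pieces.append(src[lo:hi])
        gamete = np.concatenate(pieces) if pieces else _EMPTY
    n_mut = rng.poisson(mu * L)
    if n_mut:
        gamete = np.sort(np.concatenate([gamete, rng.uniform(0, L, n_mut)]))
    return gamete


def collect_genotypes(haplotype_pairs):
    """Dosage matrix from a list of (hap1, hap2) diploids.

    Returns ``(positions, dosages)`` with ``dosages`` of shape
    (n_segregating_or_fixed_sites, n_individuals); sites are the union of
    derived positions carried by the sample, in genomic order.
    """
    all_pos = [h for pair in haplotype_pairs for h in pair]
    if not any(len(h) for h in all_pos):
        return np.empty(0), np.zeros((0, len(haplotype_pairs)), dtype=np.int16)
    positions = np.unique(np.concatenate(all_pos))
    n = len(haplotype_pairs)
    dos = np.zeros((positions.size, n), dtype=np.int16)
    for k, (h1, h2) in enumerate(haplotype_pairs):
        for h in (h1, h2):
            if len(h):
                idx = np.searchsorted(positions, h)
                dos[idx, k] += 1
    return positions, dos
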