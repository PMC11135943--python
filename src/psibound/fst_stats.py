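"""Weir & Cockerham (1984) pairwise F_ST.

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) are combined over sites as a
ratio of averages, theta = sum(a) / sum(a + b + c) -- the convention used by
genotype-based estimators and robust to low-information sites.  The summary
statistic used by the boundary-effect correction is the unweighted mean of
theta over unordered population pairs, censored below at 0.001 because
epsilon = |psi|/F_ST diverges as F_ST -> 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geno_io import MISSING, GenotypeDataset

__all__ = [
    "FstResult",
    "weir_cockerham_components",
    "pairwise_fst",
    "fst_matrix",
    "mean_pairwise_fst",
]


@dataclasses.dataclass
class FstResult:
    """Pairwise Weir-Cockerham theta matrix with censored mean."""

    populations: list
    pairwise: np.ndarray
    censor_min: float = 0.001

    @property
    def mean_pairwise(self) -> float:
        iu = np.triu_indices(len(self.populations), 1)
        return float(np.nanmean(self.pairwise[iu]))

    @property
    def censored_mean(self) -> float:
        return max(self.mean_pairwise, self.censor_min)

    @property
    def max_pair(self):
        """(pop_i, pop_j, theta) of the most differentiated pair."""
        m = self.pairwise.copy()
        np.fill_diagonal(m, -np.inf)
        m[np.isnan(m)] = -np.inf
        i, j = np.unravel_index(np.argmax(m), m.shape)
        return self.populations[i], self.populations[j], float(self.pairwise[i, j])


def _freq_het(dos):
    """Per-site allele frequency, observed het rate and called n from dosages."""
    called = dos != MISSING
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=1) / (2 * n)
        h = np.where(called, dos == 1, False).sum(axis=1) / n
    return p, h, n


def weir_cockerham_components(dosA, dosB):
    """Per-site Weir-Cockerham (1984) components (a, b, c) for two populations.

    Input is a pair of sites x individuals dosage matrices.  Sites where either
    population has fewer than 2 called individuals, or that are monomorphic in
    the pooled pair, return (0, 0, 0) and should carry no weight in the
    ratio-of-averages.
    """
    r = 2
    p1, h1, n1 = _freq_het(dosA)
    p2, h2, n2 = _freq_het(dosB)
    ok = (n1 >= 2) & (n2 >= 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    poly = ok & (pbar > 0) & (pbar < 1)
    zero = ~poly
    for comp in (a, b, c):
        comp[zero] = 0.0
    return a, b, c


def pairwise_fst(ds: GenotypeDataset, popA, popB) -> float:
    """Weir-Cockerham theta for one population pair (ratio of averages)."""
    ca = ds.pop_columns(popA)
    cb = ds.pop_columns(popB)
    a, b, c = weir_cockerham_components(ds.dosages[:, ca], ds.dosages[:, cb])
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError(f"no usable polymorphic sites for pair ({popA}, {popB})")
    return float(a.sum() / denom)


def fst_matrix(ds: GenotypeDataset, censor_min=0.001) -> FstResult:
    """Pairwise theta over all unordered pairs."""
    pops = ds.populations
    P = len(pops)
    if P < 2:
        raise ValueError("at least 2 populations required")
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            theta = pairwise_fst(ds, pops[i], pops[j])
            out[i, j] = out[j, i] = theta
    return FstResult(populations=pops, pairwise=out, censor_min=censor_min)


def mean_pairwise_fst(ds: GenotypeDataset, censor_min=0.001):
    """Unweighted mean pairwise theta and its censored value.

    Negative per-pair estimates are retained in the mean; only the mean itself
    is censored below at ``censor_min``.
    """
    res = fst_matrix(ds, censor_min=censor_min)
    return res.mean_pairwise, res.censored_mean
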