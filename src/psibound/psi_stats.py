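"""The directionality index psi and related per-population statistics.

For each population pair the two-dimensional site frequency spectrum is
projected down to a single diploid (two allele copies) per population.  The
projection is the deterministic hypergeometric expectation over all two-copy
subsamples of the called allele copies, so psi depends only on per-population
derived-allele frequencies and sample sizes, not on which individual would have
been drawn.  With

``f_ij`` = expected number of sites heterozygous in population i and fixed for
the derived allele in population j after projection, and ``S`` = expected
number of sites segregating in the projected pair,

``psi_ij = (f_ij - f_ji) / S``.

Allele surfing during an expansion drives shared derived alleles to fixation
downstream while the source stays polymorphic, so ``psi_ij > 0`` indicates
expansion from i toward j, and psi measured from the origin increases with
distance from it.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats

from .geno_io import MISSING, GenotypeDataset

__all__ = [
    "PsiResult",
    "DiversityVector",
    "projection_probs",
    "project_pair",
    "psi_pair",
    "psi_matrix",
    "binom_test_pair",
    "heterozygosity",
    "adjacent_ld",
]


@dataclasses.dataclass
class PsiResult:
    """Pairwise psi with directional counts and binomial tests.

    ``psi`` is antisymmetric with zero diagonal.  ``f_counts[i, j]`` holds the
    expected number of sites heterozygous in population i and fixed-derived in
    population j; ``seg_sites[i, j]`` the expected segregating sites of the
    projected pair.  ``p_binom`` is the exact two-sided binomial p-value of the
    rounded directional counts against a 1:1 ratio (symmetric in pair order).
    """

    populations: list
    psi: np.ndarray
    f_counts: np.ndarray
    seg_sites: np.ndarray
    p_binom: np.ndarray
    alpha: float = 0.05
    alpha_adjusted: float = np.nan

    @property
    def n_pairs(self) -> int:
        p = len(self.populations)
        return p * (p - 1) // 2

    @property
    def mean_abs_psi(self) -> float:
        iu = np.triu_indices(len(self.populations), 1)
        return float(np.nanmean(np.abs(self.psi[iu])))

    @property
    def n_significant(self) -> int:
        """Number of unordered pairs significant after Bonferroni correction."""
        iu = np.triu_indices(len(self.populations), 1)
        return int(np.nansum(self.p_binom[iu] < self.alpha_adjusted))


@dataclasses.dataclass
class DiversityVector:
    """Per-population mean expected heterozygosity ``H_E = 2p(1-p)``."""

    populations: list
    het: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.populations, self.het))


def projection_probs(derived, copies):
    """Hypergeometric probabilities of drawing 0/1/2 derived in 2 of ``copies``.

    Entries with fewer than 2 called copies are returned as 0 and must be
    masked by the caller.
    """
    d = np.asarray(derived, float)
    m = np.asarray(copies, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = m * (m - 1)
        p0 = (m - d) * (m - d - 1) / denom
        p1 = 2 * d * (m - d) / denom
        p2 = d * (d - 1) / denom
    bad = m < 2
    for p in (p0, p1, p2):
        p[bad] = 0.0
    return p0, p1, p2


def _pair_min_copies(min_called_individuals: int) -> int:
    # one called diploid individual contributes two allele copies
    return max(2, 2 * min_called_individuals)


def project_pair(ds: GenotypeDataset, popA, popB, min_called_individuals=1):
    """Project the pair 2D-SFS to one diploid per population.

    Returns ``(f_AB, f_BA, S)`` where ``f_AB`` is the expected number of sites
    heterozygous in ``popA`` and fixed-derived in ``popB``, and ``S`` the
    expected number of sites segregating in the projected pair.  Sites with
    fewer called copies than the per-population minimum in either population
    are skipped for this pair.
    """
    derived, copies = ds.derived_and_called()
    pops = ds.populations
    ia, ib = pops.index(popA), pops.index(popB)
    if copies[:, ia].max() == 0 or copies[:, ib].max() == 0:
        raise ValueError("a population has no called genotypes at any site")
    mmin = _pair_min_copies(min_called_individuals)
    valid = (copies[:, ia] >= mmin) & (copies[:, ib] >= mmin)
    p0 = {}
    p1 = {}
    p2 = {}
    for key, col in (("A", ia), ("B", ib)):
        p0[key], p1[key], p2[key] = projection_probs(derived[valid, col], copies[valid, col])
    f_ab = float(np.sum(p1["A"] * p2["B"]))
    f_ba = float(np.sum(p1["B"] * p2["A"]))
    mono = p0["A"] * p0["B"] + p2["A"] * p2["B"]
    S = float(np.sum(1.0 - mono))
    return f_ab, f_ba, S


def psi_pair(f_AB, f_BA, S):
    """psi = (f_AB - f_BA) / S; NaN with a warning when S == 0."""
    if S <= 0:
        import warnings

        warnings.warn("no segregating sites in projected pair; psi undefined")
        return np.nan
    return (f_AB - f_BA) / S


def binom_test_pair(f_AB, f_BA):
    """Exact two-sided binomial test of the directional counts against 1:1.

    Expected (possibly fractional) counts are rounded half-to-even to integers
    first.  Returns ``(p, degenerate)`` where ``degenerate`` is True when the
    rounded total is zero (p = 1 by convention).
    """
    a = int(np.rint(f_AB))
    b = int(np.rint(f_BA))
    n = a + b
    if n == 0:
        return 1.0, True
    k = min(a, b)
    # symmetric null: two-sided p = 2 P(X <= min) capped at 1
    p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
    return float(p), False


def psi_matrix(ds: GenotypeDataset, alpha=0.05, correction="bonferroni",
               min_called_individuals=1) -> PsiResult:
    """All-pairs psi, directional counts, segregating sites and binomial tests.

    Fully vectorized: per-site projection probabilities are combined across
    pairs with matrix products; sites failing the per-pair minimum-call rule
    contribute to neither counts nor the segregating-site denominator.
    """
    pops = ds.populations
    P = len(pops)
    if P < 2:
        raise ValueError("at least 2 populations required")
    derived, copies = ds.derived_and_called()
    if (copies.max(axis=0) == 0).any():
        raise ValueError("a population has no called genotypes at any site")
    mmin = _pair_min_copies(min_called_individuals)
    p0, p1, p2 = projection_probs(derived, copies)
    v = (copies >= mmin).astype(float)
    for p in (p0, p1, p2):
        p *= v

    n_valid = v.T @ v  # per-pair usable sites
    F = p1.T @ p2  # F[i, j] = f_ij = E[# sites het in i, fixed-derived in j]
    S = n_valid - p0.T @ p0 - p2.T @ p2
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = (F - F.T) / S
    np.fill_diagonal(psi, 0.0)

    p_binom = np.ones((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            p, _ = binom_test_pair(F[i, j], F[j, i])
            p_binom[i, j] = p_binom[j, i] = p
    n_pairs = P * (P - 1) // 2
    alpha_adj = alpha / n_pairs if correction == "bonferroni" else alpha
    return PsiResult(
        populations=pops,
        psi=psi,
        f_counts=F,
        seg_sites=S,
        p_binom=p_binom,
        alpha=alpha,
        alpha_adjusted=alpha_adj,
    )


def heterozygosity(ds: GenotypeDataset) -> DiversityVector:
    """Per-population expected heterozygosity 2p(1-p), averaged over sites."""
    derived, copies = ds.derived_and_called()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = derived / copies
    het = 2 * p * (1 - p)
    het = np.where(copies > 0, het, np.nan)
    return DiversityVector(populations=ds.populations,
                           het=np.nanmean(het, axis=0))


def adjacent_ld(ds: GenotypeDataset, threshold=0.2,
                positions: Optional[np.ndarray] = None):
    """Fraction of physically adjacent SNP pairs with r^2 above ``threshold``.

    r^2 is the squared Pearson correlation of derived-allele dosages across all
    individuals (complete cases per pair).  Pairs with a monomorphic member are
    skipped.  Returns ``(fraction, n_pairs_used)``.
    """
    pos = positions if positions is not None else ds.positions
    if pos is None:
        raise ValueError("site positions are required for the LD check")
    if ds.n_sites < 2:
        raise ValueError("need at least 2 sites")
    order = np.argsort(pos, kind="stable")
    X = ds.dosages[order].astype(float)
    X[ds.dosages[order] == MISSING] = np.nan

    a, b = X[:-1], X[1:]
    both = ~np.isnan(a) & ~np.isnan(b)
    n = both.sum(axis=1)
    a0 = np.where(both, a, 0.0)
    b0 = np.where(both, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a0.sum(1) / n
        mb = b0.sum(1) / n
        cov = (a0 * b0).sum(1) / n - ma * mb
        va = (a0 ** 2).sum(1) / n - ma ** 2
        vb = (b0 ** 2).sum(1) / n - mb ** 2
        r2 = cov ** 2 / (va * vb)
    ok = (n >= 2) & (va > 1e-12) & (vb > 1e-12)
    if not ok.any():
        return np.nan, 0
    return float((r2[ok] > threshold).mean()), int(ok.sum())
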