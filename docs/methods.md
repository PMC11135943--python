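# Methods

This document describes the statistical and simulation methods implemented in
`psibound`. The package quantifies how *boundary effects* (BEs) — the loss of
migrants at the edges of a species range — mimic the genetic footprint of a
*range expansion* (RE), and provides a calibrated scale to tell the two apart.

## 1. The directionality index ψ

### 1.1 Definition

For a pair of populations *i*, *j*, the two-dimensional site frequency
spectrum (2D-SFS) of derived-allele counts is projected down to two allele
copies per population with the hypergeometric projection. For a site with
*n* called allele copies and *k* derived copies in one population, the
probability that a projected draw of 2 copies contains *d* derived copies is

    P(d | k, n) = C(k, d) C(n − k, 2 − d) / C(n, 2),   d ∈ {0, 1, 2}.

Let `p0, p1, p2` be the per-site projected probabilities of 0, 1, 2 derived
copies. Define

    f_ij = Σ_sites p1(i) · p2(j)   (expected # sites heterozygous in i and
                                    fixed derived in j after projection)
    S    = Σ_sites [1 − p0(i)p0(j) − p2(i)p2(j)]   (expected # segregating
                                                    projected sites)
    ψ_ij = (f_ij − f_ji) / S.

ψ is antisymmetric with a zero diagonal by construction. During a range
expansion, serial founder events let rare variants *surf* on the wave front
and reach fixation in downstream populations while the source stays
polymorphic. Hence `f_ij > f_ji`, i.e. **ψ_ij > 0, indicates expansion from
i toward j**, and ψ measured from the true origin increases with distance.

Projection to 2 copies makes ψ invariant to unequal sample sizes and missing
data; sites without at least one called diploid in each population of the
pair are excluded.

### 1.2 Significance

The counts `a = f_ij`, `b = f_ji` are (approximately) exchangeable under the
null of no directionality, so each pair is tested with an exact two-sided
binomial test of `round(a)` successes in `round(a + b)` trials at P = 1/2
(rounding is half-to-even):

    p = min(1, 2 · BinomCDF(min(a, b); a + b, 0.5)).

E.g. counts (10, 0) give p = 2 · 0.5^10 = 0.001953125. Across all P(P−1)/2
pairs a Bonferroni correction is applied. This per-pair test treats projected
SNPs as independent, which is adequate when adjacent-SNP linkage
disequilibrium is weak (see §5).

## 2. F_ST and the relative asymmetry ε

Pairwise F_ST is the Weir–Cockerham (1984) θ for two populations: per-site
variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed with the standard
formulas for r = 2 sampled populations, and θ is the ratio of averages
Σa / Σ(a+b+c) over sites. Sites with fewer than two called individuals in
either population, or monomorphic in the pooled pair, contribute nothing.

The boundary-effect scale is built from

    ε = mean_pairs |ψ| / max(mean_pairs F_ST, 0.001),

the mean absolute directionality per unit of overall differentiation. The
0.001 censor keeps ε finite in panmictic-like data where the F_ST estimate
can be ≈ 0 or slightly negative; e.g. mean |ψ| = 0.0134 with negative mean
F_ST gives ε = 0.0134/0.001 = 13.4.

## 3. Origin inference

### 3.1 TDoA (time difference of arrival)

A grid of candidate origins is scanned (by default 100 × 100 over the padded
sampling bounding box; for lattice data the candidate set can be restricted
to the sampled populations). For candidate g and each unordered pair (i, j)
the predictor is the distance difference `dd_ij(g) = d(g, j) − d(g, i)`; an
OLS regression of ψ_ij on dd_ij(g) is fitted at every grid point and the
origin estimate is the qualifying grid point (positive slope) with the
highest r². The pairwise observations are strongly non-independent, so the
regression p-values are **anti-conservative by construction** and are
exposed only as `p_descriptive`. Ties in r² are broken toward the centroid
of the sampled populations; estimates landing on the padded grid boundary
are flagged.

The same machinery accepts the antisymmetric heterozygosity-difference
matrix Δ_ij = H_i − H_j, since expected heterozygosity decays away from an
expansion origin.

### 3.2 Non-TDoA focal scan

For each focal population, ψ(focal, ·) is regressed on distance from the
focal population over the remaining P − 1 populations. These observations
are not reused across regressions, so the OLS degrees of freedom are honest.
The focal population with the strongest positive-slope r² is the non-TDoA
origin estimate, and that r² is the effect size

    τ = max_focal r²(ψ ~ distance).

τ from this scan is the default effect size of the E model (§4); the TDoA
analogue τ_TDoA (best grid-point r²) is also reported.

## 4. The E scale: separating expansions from boundary effects

Equilibrium metapopulations with closed boundaries show nonzero ψ clines
pointing at the habitat center — a pure boundary effect. The package
calibrates the *expected equilibrium asymmetry* ε_eq by simulation and
expresses observations as the fold excess

    E = ε / ε_eq.

ε_eq is estimated per simulated scenario as ε at the last (equilibrated)
sampling time. Over a suite of simulated scenarios (1D and 2D stepping-stone
expansions at several migration rates, plus panmictic controls, at many
times since expansion), E is regressed on the observables:

    E = β0 + β_ε ε + β_τ τ + β_ετ (ε·τ) + error,

fitted by weighted least squares with weights 1/ε (residual spread grows
with ε). A reference-scale fit gives coefficients ≈ (1.00, 0.0914, −0.894,
3.38); evaluating it at (ε, τ) = (1.05, 0.58) yields E ≈ 2.64.

For a new data set the model reports Ê and a one-sided lower prediction
bound at level α,

    lower = Ê − t_{1−α, df} · sqrt(xᵀ Cov(β) x + s²·ε),

and the data are declared RE-supported only if the lower bound exceeds 1
(the equilibrium expectation). Records with E_true > 1.2 are classified as
nonequilibrium during calibration; the false-positive criterion is that no
equilibrium record crosses the Bonferroni-corrected E > 1 boundary.
Evaluations outside the calibrated (ε, τ) ranges are flagged as
extrapolations.

## 5. Simulators

### 5.1 Stepping-stone (forward, individual-based)

A non-Wright–Fisher model of a hermaphroditic, non-selfing species with
non-overlapping generations on a 1D chain or 2D lattice of demes. Each
individual draws Poisson(offspring_mean) offspring with a random non-self
mate from its deme; deme size is truncated at carrying capacity K; each
individual then emigrates with total probability M, split uniformly over the
2·dims lattice directions (moves off the grid are cancelled). Genomes are
single linear chromosomes; gametes are formed with Poisson-distributed
crossovers and new mutations at rate μ per bp (infinite-sites on continuous
coordinates). A single origin deme is burned in, the rest of the grid starts
empty, and t₀ is the cycle when the census reaches 98% of K·N. Genotypes of
n diploids per deme are sampled at fixed cycles after t₀.

The reference scale is 81 demes of K = 1000; the desk scale used by the
tests and the bundled calibration suite is 8–25 demes of K = 25–50 with
offspring_mean = 2.0 (at small K the default growth rate of 1.04 cannot
offset migrant loss into sub-pair frontier demes).

A matching coalescent fixture (msprime) generates *equilibrium*
stepping-stone data directly: per-adjacent-pair migration rate M/2 (1D) or
M/4 (2D) reproduces the forward model's total-emigration convention. It
supports unlinked-SNP accumulation, a fully linked chromosome with uniform
recombination, and a panmictic single-pool mode.

### 5.2 Continuous space (forward, individual-based)

An age-structured, iteroparous, hermaphroditic model on a habitat-quality
raster q ∈ [0, 1]. Fitness is f = (k·q/c)(1 − m[age]) clamped to [0, 1],
with age-specific mortality m = (0.7, 0, 0, 0.25, 0.5, 0.75, 1.0), local
competition c computed from a 3 × 3 neighborhood, and k a density-scaling
constant. Adults (age ≥ 1) reproduce with Poisson(1) offspring and a random
non-self mate within a mating radius. Dispersal proposes eight random
directions with distance U(0,1)·q·d_max; each straight-line path accumulates
resistance Σ(1 − q) over the raster cells it crosses (supercover
rasterization), paths crossing q = 0 or leaving the map are discarded,
s > s_max = 8 is disallowed, and one proposal is chosen with weight
1 − s/s_max. An individual with no viable proposal dies (absorbing
boundaries). REs seed the leftmost 10% of columns during burn-in; the DE
(demographic expansion) control reseeds the whole map after burn-in.
Sampling selects population cores by k-means and takes the nearest
individuals per core.

## 6. Linkage disequilibrium check

The per-pair binomial test assumes approximately independent SNPs. The
package reports the fraction of physically adjacent SNP pairs with r² > 0.2
(squared Pearson correlation of pooled dosages). Note that in strongly
structured samples this pooled r² includes mixture (admixture) LD generated
by population structure itself, which does not decay with map distance; the
fraction should be compared against a structure-matched baseline rather than
zero.

## 7. Pipeline

`run_full_analysis` chains the pieces: optional MAF filtering (default
threshold 1/(2n)) and SNP subsampling → ψ matrix with per-pair binomial
tests → pairwise F_ST → TDoA surface and focal scan (ψ, and Δhet when
available) → ε, τ → optional adjacent-LD check → optional E-model decision.
`calibrate_model` runs a simulation suite and fits the E model;
`classify_records` summarizes detection power and false-positive rates. The
`psibound` command-line interface exposes each step (`convert`, `psi`,
`fst`, `origin`, `etest`, `simulate`, `calibrate`, `report`).
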