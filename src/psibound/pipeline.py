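"""End-to-end analysis and model-calibration pipelines.

``run_full_analysis`` takes one polarized genotype data set and produces a
:class:`RunReport`: pairwise psi with binomial tests, pairwise Weir-Cockerham
F_ST, the TDoA origin surface, the per-focal-population scan, epsilon and --
when a fitted :class:`~psibound.escale_model.EModel` is supplied -- the
boundary-effect-corrected range-expansion decision.

``calibrate_model`` builds the calibration suite behind that decision: a set
of forward stepping-stone simulations (range expansions sampled on a time
series, plus equilibrium references) reduced to
:class:`~psibound.escale_model.EpsilonRecord` rows, with ``epsilon_eq`` taken
from the final sampling time of the same replicate, then fitted by weighted
least squares.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .geno_io import GenotypeDataset, FilterConfig, filter_maf, subsample_snps
from .psi_stats import PsiResult, psi_matrix, heterozygosity, adjacent_ld
from .fst_stats import FstResult, fst_matrix
from .origin_infer import (
    OriginSurface,
    FocalScan,
    tdoa_surface,
    non_tdoa_scan,
    delta_het_matrix,
)
from .escale_model import EModel, EpsilonRecord, epsilon, fit_E_model, predict_E
from .steppingstone_sim import SteppingStoneConfig, run_stepping_stone, run_panmictic

__all__ = ["RunReport", "run_full_analysis", "calibrate_model", "records_from_simulation"]


@dataclasses.dataclass
class RunReport:
    """All statistics of one data set, with an optional corrected RE decision."""

    psi: PsiResult
    fst: FstResult
    surface: OriginSurface
    scan: FocalScan
    het_surface: Optional[OriginSurface]
    epsilon: float
    tau_tdoa: float
    tau_non_tdoa: float
    ld_fraction: Optional[float] = None
    ld_pairs: int = 0
    decision: Optional[dict] = None   # predict_E output when a model was given
    n_sites: int = 0
    n_populations: int = 0

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        bi, bj, btheta = self.fst.max_pair
        out = {
            "n_sites": self.n_sites,
            "n_populations": self.n_populations,
            "mean_abs_psi": self.psi.mean_abs_psi,
            "n_significant_pairs": self.psi.n_significant,
            "n_pairs": self.psi.n_pairs,
            "mean_fst": self.fst.mean_pairwise,
            "censored_fst": self.fst.censored_mean,
            "max_fst_pair": [bi, bj, btheta],
            "epsilon": self.epsilon,
            "tau_tdoa": self.tau_tdoa,
            "tau_non_tdoa": self.tau_non_tdoa,
            "origin_tdoa": list(map(float, self.surface.best_origin)),
            "origin_no_cline": self.surface.no_cline,
            "origin_on_padding_boundary": self.surface.on_padding_boundary,
            "best_focal_population": self.scan.best_pop,
        }
        if self.het_surface is not None:
            out["origin_het"] = list(map(float, self.het_surface.best_origin))
        if self.ld_fraction is not None:
            out["adjacent_ld_fraction"] = self.ld_fraction
            out["adjacent_ld_pairs"] = self.ld_pairs
        if self.decision is not None:
            out["decision"] = self.decision
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.summary(), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_full_analysis(ds: GenotypeDataset, model: Optional[EModel] = None,
                      grid_size=100, maf: Optional[FilterConfig] = None,
                      alpha=0.05, check_ld=False, grid=None) -> RunReport:
    """psi, F_ST, origin surfaces, epsilon and (optionally) the RE decision.

    ``maf`` applies a frequency filter first (monomorphic sites are always
    dropped).  ``check_ld`` adds the adjacent-SNP r^2 diagnostic (requires
    genomic positions).  ``model`` enables the corrected decision: the data set
    supports a range expansion when the one-sided lower prediction bound for
    E = epsilon/epsilon_eq exceeds 1.
    """
    if maf is not None:
        ds = filter_maf(ds, maf)
        if maf.n_subsample is not None and maf.n_subsample < ds.n_sites:
            ds = subsample_snps(ds, maf.n_subsample, maf.seed)
    psi = psi_matrix(ds, alpha=alpha)
    fst = fst_matrix(ds)
    coords = ds.pop_coords()
    surface = tdoa_surface(psi.psi, coords, G=grid_size, statistic="psi",
                           lonlat=ds.lonlat, grid=grid)
    scan = non_tdoa_scan(psi.psi, coords, populations=ds.populations,
                         statistic="psi", lonlat=ds.lonlat)
    het_surface = None
    if ds.n_sites:
        div = heterozygosity(ds)
        if np.isfinite(div.het).all():
            het_surface = tdoa_surface(delta_het_matrix(div), coords,
                                       G=grid_size, statistic="het",
                                       lonlat=ds.lonlat, grid=grid)
    eps = epsilon(psi.mean_abs_psi, fst.mean_pairwise)
    ld_frac, ld_pairs = (None, 0)
    if check_ld:
        ld_frac, ld_pairs = adjacent_ld(ds)
    decision = None
    if model is not None:
        decision = predict_E(model, eps, surface.tau_tdoa, alpha=alpha)
    return RunReport(
        psi=psi,
        fst=fst,
        surface=surface,
        scan=scan,
        het_surface=het_surface,
        epsilon=eps,
        tau_tdoa=surface.tau_tdoa,
        tau_non_tdoa=scan.tau_non_tdoa,
        ld_fraction=ld_frac,
        ld_pairs=ld_pairs,
        decision=decision,
        n_sites=ds.n_sites,
        n_populations=len(ds.populations),
    )


def records_from_simulation(sim, source, tau_mode="tdoa", grid_size=25):
    """EpsilonRecords for every sampling time of one simulation replicate.

    ``epsilon_eq`` is the epsilon at the replicate's final (latest) sampling
    time, the operational stand-in for the migration-drift equilibrium value.
    """
    records = []
    cycles = sorted(sim.samples)
    if not cycles:
        return records
    by_cycle = {}
    for cyc in cycles:
        ds = sim.samples[cyc]
        psi = psi_matrix(ds)
        fst = fst_matrix(ds)
        coords = ds.pop_coords()
        if tau_mode == "tdoa":
            tau = tdoa_surface(psi.psi, coords, G=grid_size).tau_tdoa
        else:
            tau = non_tdoa_scan(psi.psi, coords).tau_non_tdoa
        by_cycle[cyc] = (psi.mean_abs_psi, fst.censored_mean, tau)
    eps_eq = epsilon(by_cycle[cycles[-1]][0], by_cycle[cycles[-1]][1])
    for cyc in cycles:
        m_psi, fst_c, tau = by_cycle[cyc]
        records.append(EpsilonRecord(
            mean_abs_psi=m_psi,
            fst_censored=fst_c,
            tau=tau,
            epsilon_eq=eps_eq,
            source=source,
            cycle=cyc,
        ))
    return records


def calibrate_model(configs: Optional[Sequence[tuple]] = None, seed=0,
                    tau_mode="tdoa", terms="full", n_reps=1,
                    progress=None):
    """Fit the E model from a suite of forward simulations.

    ``configs`` is a sequence of ``(source, SteppingStoneConfig)`` pairs;
    sources starting with "RE"/"1D"/"2D" are treated as expansions and
    "panmictic"/"DE" as equilibrium references by downstream classification.
    When omitted, a reduced desk-scale suite (small 1D and 2D lattices at
    three migration rates, plus a panmictic control) is used.  Each config is
    replicated ``n_reps`` times with distinct seeds.

    Returns ``(EModel, records)``.
    """
    rng = np.random.default_rng(seed)
    if configs is None:
        configs = _default_suite()
    records = []
    for source, cfg in configs:
        for rep in range(n_reps):
            c = dataclasses.replace(cfg, seed=int(rng.integers(2 ** 31 - 1)))
            runner = run_panmictic if source == "panmictic" else run_stepping_stone
            sim = runner(c)
            if not sim.completed:
                continue
            got = records_from_simulation(sim, source, tau_mode=tau_mode)
            records.extend(got)
            if progress is not None:
                progress(source, rep, len(got))
    model = fit_E_model(records, terms=terms)
    return model, records


def _default_suite():
    """Desk-scale calibration suite: 1D/2D expansions and a panmictic control.

    The growth rate is raised well above the reference experiment's 1.04: with
    tiny demes the stochastic loss of sub-pair migrant packets at the expansion
    front exceeds a 4% growth margin and the expansion stalls.
    """
    times = (50, 100, 200, 400, 800, 1600)
    common = dict(K=30, origin=0, offspring_mean=2.0, burn_in_cycles=500,
                  mu=5e-7, r=5e-7, sample_times=times, n_sample_per_deme=5)
    suite = []
    for M in (0.01, 0.05, 0.1):
        suite.append((f"1D_M{M}", SteppingStoneConfig(
            n_demes=12, dims=1, migration=M, **common)))
        suite.append((f"2D_M{M}", SteppingStoneConfig(
            n_demes=16, dims=2, migration=M, **common)))
    suite.append(("panmictic", SteppingStoneConfig(
        n_demes=12, dims=1, migration=0.1, **common)))
    return suite
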