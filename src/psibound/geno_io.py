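"""Genotype and coordinate I/O.

The in-memory container is :class:`GenotypeDataset`: a sites x individuals
matrix of derived-allele dosages (0/1/2, -1 for missing calls) together with an
individual -> population map and per-population planar (or lon/lat)
coordinates.  Two on-disk formats are supported:

* a tab-separated genotype table, sites as rows, with columns
  ``site_id``, ``pos`` and one column per individual, accompanied by a
  population map TSV with columns ``individual``, ``population``, ``x``, ``y``;
* VCF with an ancestral-allele INFO tag (default ``AA``); sites whose
  ancestral allele matches ALT are recoded to derived dosage ``2 - g`` and
  sites with unknown ancestral state are dropped (and counted).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "FilterConfig",
    "read_popmap",
    "read_genotypes",
    "write_genotypes",
    "filter_maf",
    "subsample_snps",
]


@dataclasses.dataclass
class GenotypeDataset:
    """Polarized biallelic SNP dosages with population labels and coordinates.

    Attributes
    ----------
    dosages:
        ``(n_sites, n_individuals)`` integer array of derived-allele counts in
        {0, 1, 2, MISSING}.
    site_ids:
        Per-site identifiers (strings).
    positions:
        Per-site genomic positions used for adjacent-SNP LD; monotone order is
        not required on input but sites are kept in file order.
    individuals:
        Column labels of ``dosages``.
    pop_of:
        Mapping individual -> population label (dict-like).
    coords:
        DataFrame indexed by population with columns ``x`` and ``y``.
    polarized:
        True when ancestral states are known (derived orientation).
    lonlat:
        When True, coordinates are longitude/latitude and great-circle
        distances are used downstream.
    """

    dosages: np.ndarray
    site_ids: np.ndarray
    pop_of: dict
    coords: pd.DataFrame
    individuals: np.ndarray
    positions: Optional[np.ndarray] = None
    polarized: bool = True
    lonlat: bool = False
    n_dropped_unpolarized: int = 0

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a sites x individuals matrix")
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.individuals = np.asarray(self.individuals, dtype=object)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")
        missing_pops = [i for i in self.individuals if i not in self.pop_of]
        if missing_pops:
            raise ValueError(f"individuals absent from population map: {missing_pops[:5]}")
        pops = set(self.pop_of[i] for i in self.individuals)
        absent = pops - set(self.coords.index)
        if absent:
            raise ValueError(f"populations without coordinates: {sorted(absent)[:5]}")
        if len(pops) < 2:
            raise ValueError("at least 2 populations are required")

    # -- helpers ----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list:
        """Population labels in coords order, restricted to sampled pops."""
        sampled = {self.pop_of[i] for i in self.individuals}
        return [p for p in self.coords.index if p in sampled]

    def pop_columns(self, pop) -> np.ndarray:
        """Column indices of individuals belonging to ``pop``."""
        return np.array([k for k, ind in enumerate(self.individuals)
                         if self.pop_of[ind] == pop], dtype=int)

    def pop_coords(self) -> np.ndarray:
        """(P, 2) coordinate array in :attr:`populations` order."""
        return self.coords.loc[self.populations, ["x", "y"]].to_numpy(float)

    def derived_and_called(self):
        """Per-population derived-allele and called-copy counts.

        Returns ``(derived, copies)``, both ``(n_sites, P)`` arrays where
        ``copies`` is the number of successfully called allele copies.
        """
        pops = self.populations
        S = self.n_sites
        derived = np.zeros((S, len(pops)))
        copies = np.zeros((S, len(pops)))
        for j, p in enumerate(pops):
            cols = self.pop_columns(p)
            sub = self.dosages[:, cols]
            called = sub != MISSING
            derived[:, j] = np.where(called, sub, 0).sum(axis=1)
            copies[:, j] = 2 * called.sum(axis=1)
        return derived, copies

    def take_sites(self, idx) -> "GenotypeDataset":
        return dataclasses.replace(
            self,
            dosages=self.dosages[idx],
            site_ids=self.site_ids[idx],
            positions=None if self.positions is None else self.positions[idx],
        )


@dataclasses.dataclass
class FilterConfig:
    """Site filtering: minor-allele-frequency threshold and SNP subsampling.

    ``maf_threshold=None`` uses the default 1/(2n) for n diploids in the whole
    sample, which keeps every segregating site (singletons included).
    """

    maf_threshold: Optional[float] = None
    n_subsample: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.maf_threshold is not None and not (0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must be in [0, 0.5)")


# -- population map ---------------------------------------------------------

def read_popmap(path):
    """Read a population map TSV (individual, population, x, y).

    Returns ``(pop_of, coords)``.  Coordinates must be identical for all
    individuals of a population.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str})
    required = {"individual", "population", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map must have columns {sorted(required)}")
    pop_of = dict(zip(df["individual"], df["population"]))
    coords = df.groupby("population")[["x", "y"]].first()
    spread = df.groupby("population")[["x", "y"]].nunique()
    if (spread > 1).any().any():
        raise ValueError("inconsistent coordinates within a population")
    return pop_of, coords


def write_popmap(ds: GenotypeDataset, path):
    rows = [
        {
            "individual": ind,
            "population": ds.pop_of[ind],
            "x": ds.coords.loc[ds.pop_of[ind], "x"],
            "y": ds.coords.loc[ds.pop_of[ind], "y"],
        }
        for ind in ds.individuals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- genotype table ---------------------------------------------------------

def _read_table(path, pop_of, coords, lonlat):
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    if "site_id" not in df.columns:
        raise ValueError("genotype table must have a 'site_id' column")
    positions = df["pos"].to_numpy(float) if "pos" in df.columns else None
    ind_cols = [c for c in df.columns if c not in ("site_id", "pos")]
    dosages = df[ind_cols].to_numpy()
    return GenotypeDataset(
        dosages=dosages.astype(np.int16),
        site_ids=df["site_id"].to_numpy(object),
        positions=positions,
        individuals=np.array(ind_cols, dtype=object),
        pop_of=pop_of,
        coords=coords,
        lonlat=lonlat,
    )


def write_genotypes(ds: GenotypeDataset, path):
    """Write the TSV genotype table (sites as rows, MISSING as -1)."""
    data = {"site_id": ds.site_ids}
    if ds.positions is not None:
        data["pos"] = ds.positions
    for k, ind in enumerate(ds.individuals):
        data[str(ind)] = ds.dosages[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# -- VCF ---------------------------------------------------------------------

def _read_vcf(path, pop_of, coords, lonlat, aa_tag="AA"):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = np.array(vcf.samples, dtype=object)
    rows, ids, pos = [], [], []
    dropped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            dropped += 1
            continue
        aa = var.INFO.get(aa_tag)
        if aa is None:
            dropped += 1
            continue
        aa = str(aa).upper()
        g = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING)
        if aa == var.REF.upper():
            pass
        elif aa == var.ALT[0].upper():
            dos = np.where(dos == MISSING, MISSING, 2 - dos)
        else:
            dropped += 1
            continue
        rows.append(dos.astype(np.int16))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        pos.append(var.POS)
    if not rows:
        raise ValueError("no polarizable biallelic SNPs in VCF")
    return GenotypeDataset(
        dosages=np.array(rows, dtype=np.int16),
        site_ids=np.array(ids, dtype=object),
        positions=np.array(pos, float),
        individuals=individuals,
        pop_of=pop_of,
        coords=coords,
        lonlat=lonlat,
        n_dropped_unpolarized=dropped,
    )


def read_genotypes(path, format="table", popmap=None, pop_of=None, coords=None,
                   lonlat=False, aa_tag="AA") -> GenotypeDataset:
    """Read genotypes from ``table`` or ``vcf`` format.

    Either ``popmap`` (path to the TSV population map) or both ``pop_of`` and
    ``coords`` must be given.
    """
    if popmap is not None:
        pop_of, coords = read_popmap(popmap)
    if pop_of is None or coords is None:
        raise ValueError("a population map is required")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_table(path, pop_of, coords, lonlat)
    if format == "vcf":
        return _read_vcf(path, pop_of, coords, lonlat, aa_tag=aa_tag)
    raise ValueError(f"unknown format: {format!r}")


# -- filtering ---------------------------------------------------------------

def _pooled_maf(ds: GenotypeDataset):
    called = ds.dosages != MISSING
    copies = 2 * called.sum(axis=1)
    derived = np.where(called, ds.dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = derived / copies
    freq = np.where(copies > 0, freq, 0.0)
    return np.minimum(freq, 1.0 - freq), copies


def filter_maf(ds: GenotypeDataset, cfg: FilterConfig | None = None) -> GenotypeDataset:
    """Retain sites with pooled minor-allele frequency >= threshold.

    The boundary is inclusive so that with the default threshold 1/(2n) every
    segregating site (singletons included) survives; monomorphic sites are
    always removed.
    """
    cfg = cfg or FilterConfig()
    threshold = cfg.maf_threshold
    if threshold is None:
        threshold = 1.0 / (2 * ds.n_individuals)
    maf, copies = _pooled_maf(ds)
    keep = (maf >= threshold) & (maf > 0) & (copies > 0)
    if not keep.any():
        raise ValueError(f"all sites removed at maf threshold {threshold}")
    return ds.take_sites(np.flatnonzero(keep))


def subsample_snps(ds: GenotypeDataset, k: int, seed: int) -> GenotypeDataset:
    """Uniform random subset of ``k`` sites without replacement (site order kept)."""
    if k > ds.n_sites:
        raise ValueError(f"cannot subsample {k} from {ds.n_sites} sites")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(ds.n_sites, size=k, replace=False))
    return ds.take_sites(idx)
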