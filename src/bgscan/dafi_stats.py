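"""The per-individual average derived allele frequency, DAF̄ᵢ.

For a set of S_tot sites polymorphic in the full sample, individual i's
average derived allele frequency is

    DAF̄ᵢ = n_i / (2 · S_tot),    n_i = Het_i + 2·HomDer_i ,

i.e. the number of derived alleles the individual carries over twice the
number of polymorphic sites.  Under neutrality E(n_i) = 2·u·t_global for
every individual regardless of its population's demography, so
E(DAF̄ᵢ) = t̄_global / T̄_tot — the sample TMRCA over the total genealogy
length — making DAF̄ᵢ a demography-invariant probe of selection at linked
sites: background selection lowers it, gBGC raises (WS) or lowers (SW) it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SnpTable


@dataclass
class TheoryQuantities:
    """Coalescent quantities behind the expectation of DAF̄ᵢ.

    Times in generations (or any common unit — only ratios matter):
    ``t_global`` the sample TMRCA, ``t_tot`` the total tree length, ``u``
    the per-site per-generation mutation rate, ``t_i`` optional
    within-individual coalescence times.
    """

    t_global: float
    t_tot: float
    u: float = 1.0
    t_i: np.ndarray | None = None

    def __post_init__(self):
        if self.t_tot < self.t_global:
            raise ValueError("total tree length below TMRCA")
        if self.t_i is not None and np.any(np.asarray(self.t_i) > self.t_global):
            raise ValueError("within-individual time exceeds TMRCA")


def expected_dafi(theory: TheoryQuantities) -> float:
    """E(DAF̄ᵢ) = t̄_global / T̄_tot (scale-free)."""
    if theory.t_tot <= 0:
        raise ValueError("total tree length must be positive")
    return theory.t_global / theory.t_tot


def derived_allele_count(dosages) -> tuple[int, int, int]:
    """(n_i, het_i, homder_i) from one individual's dosage vector."""
    d = np.asarray(dosages)
    if d.size and (d.min() < 0 or d.max() > 2):
        raise ValueError("dosage outside {0,1,2}")
    het = int(np.count_nonzero(d == 1))
    homder = int(np.count_nonzero(d == 2))
    return het + 2 * homder, het, homder


@dataclass
class DafiResult:
    """Per-individual DAF̄ᵢ over one site subset (shared denominator)."""

    sample_ids: list[str]
    populations: list[str]
    regions: list[str]
    n_i: np.ndarray           # derived-allele count per individual
    s_tot: int                # polymorphic sites in the subset
    dafi: np.ndarray = field(init=False)

    def __post_init__(self):
        self.dafi = self.n_i / (2.0 * self.s_tot)

    def group_means(self, by: str = "region") -> dict[str, float]:
        labels = self.regions if by == "region" else self.populations
        out: dict[str, list[float]] = {}
        for lab, v in zip(labels, self.dafi):
            out.setdefault(lab, []).append(float(v))
        return {k: float(np.mean(v)) for k, v in out.items()}

    def mean(self) -> float:
        return float(self.dafi.mean())


def dafi_from_matrix(dosages, populations=None, regions=None,
                     sample_ids=None) -> DafiResult:
    """DAF̄ᵢ directly from a (sites × individuals) dosage matrix."""
    dos = np.asarray(dosages, dtype=np.int64)
    if dos.ndim != 2 or dos.shape[0] == 0:
        raise ValueError("no polymorphic sites in subset")
    n_ind = dos.shape[1]
    if populations is None:
        populations = ["pop0"] * n_ind
    if regions is None:
        regions = list(populations)
    if sample_ids is None:
        sample_ids = [f"ind{j}" for j in range(n_ind)]
    return DafiResult(list(sample_ids), list(populations), list(regions),
                      dos.sum(axis=0), dos.shape[0])


def dafi(table: SnpTable, site_mask=None) -> DafiResult:
    """DAF̄ᵢ for every individual over a site subset.

    ``site_mask`` is a boolean mask / index array over the table's records
    (default: all).  Sites are assumed already restricted to those
    polymorphic in the full selected sample — the subset never re-tests
    polymorphism, so all individuals share the denominator 2·S_tot.
    """
    if site_mask is None:
        sub = table
    else:
        sub = table.subset(site_mask)
    if len(sub) == 0:
        raise ValueError("no polymorphic sites in subset")
    dos = sub.dosage_matrix().astype(np.int64)
    n_i = dos.sum(axis=0)
    return DafiResult([i.sample_id for i in sub.individuals],
                      [i.population for i in sub.individuals],
                      [i.region for i in sub.individuals],
                      n_i, len(sub))


def dafi_by_bin(table, bins: np.ndarray | None = None) -> dict[int, DafiResult]:
    """Independent DAF̄ᵢ per recombination bin (bin-specific S_tot,b).

    ``bins`` defaults to the table's 'bin' annotation; bin 0 (unbinned /
    missing rate) is excluded.  Empty bins are skipped with a warning.
    """
    if bins is None:
        bins = table.annotations["bin"]
    bins = np.asarray(bins)
    out: dict[int, DafiResult] = {}
    for b in sorted(set(bins.tolist()) - {0}):
        mask = bins == b
        if not mask.any():
            warnings.warn(f"empty recombination bin {b}")
            continue
        out[b] = dafi(table, mask)
    return out


def dafi_curve(table, by: str = "region") -> "pd.DataFrame":
    """Tidy per-bin group-mean DAF̄ᵢ table (the Figure-1-style curve)."""
    import pandas as pd
    rr = table.annotations["rr_cMMb"]
    bins = table.annotations["bin"]
    rows = []
    for b, res in dafi_by_bin(table).items():
        mean_rr = float(np.nanmean(rr[bins == b]))
        for group, value in res.group_means(by).items():
            rows.append({"bin": b, "mean_rr": mean_rr, "group": group,
                         "dafi": value, "s_tot": res.s_tot})
    return pd.DataFrame(rows)
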