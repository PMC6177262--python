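"""Forward-in-time Wright–Fisher simulator of background selection.

The simulated genome is a linear sequence of identical regions, each a
selected stretch (deleterious mutations, fitness 1-s homozygous, 1-s/2
heterozygous, multiplicative across sites) followed by a neutral stretch.
Discrete generations: parents drawn proportional to fitness, per-gamete
crossovers Poisson(r·L) at uniform positions, new mutations Poisson(u·L)
per haplotype under infinite sites (continuous positions within bp slots).
Demography supports piecewise-constant sizes, fixed-duration bottlenecks and
a single-pulse admixture from a neutrally evolving ghost population.

Summary statistics (DAF̄ᵢ, projected SFS) are computed on neutral-stretch
mutations only, as linked-neutral diversity is the object of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import sfs_toolkit

#: hard cap on simultaneously tracked segregating sites
MAX_SEGREGATING = 500_000

BOTTLENECK_DURATION = 100   # generations, fixed


@dataclass(frozen=True)
class GenomeArchitecture:
    """Interleaved selected/neutral genome layout."""

    n_regions: int = 1000
    sel_len: int = 1000     # bp under purifying selection per region
    neu_len: int = 4000     # neutral bp per region

    def __post_init__(self):
        if min(self.n_regions, self.sel_len, self.neu_len) <= 0:
            raise ValueError("architecture lengths must be positive")

    @property
    def region_len(self) -> int:
        return self.sel_len + self.neu_len

    @property
    def length(self) -> int:
        return self.n_regions * self.region_len

    def is_selected(self, pos: np.ndarray) -> np.ndarray:
        return np.mod(pos, self.region_len) < self.sel_len

    @classmethod
    def fine(cls) -> "GenomeArchitecture":
        """Alternative layout: 10,000 regions of 100 bp selected + 400 bp."""
        return cls(10_000, 100, 400)


@dataclass(frozen=True)
class SelectionParams:
    """Selection and rate parameters.

    ``s`` is the magnitude of the deleterious effect (s=0 neutral):
    heterozygotes have fitness 1-s/2, homozygotes 1-s.  ``u`` is the
    per-site per-generation mutation rate (same for both site classes),
    ``r`` the per-bp per-generation crossover rate.
    """

    s: float = 0.1
    u: float = 1.25e-7
    r: float = 1e-8

    def __post_init__(self):
        if not (0 <= self.s < 1):
            raise ValueError("s must be in [0, 1)")
        if self.u < 0 or self.r < 0:
            raise ValueError("u and r must be non-negative")


@dataclass(frozen=True)
class AdmixturePulse:
    gen: int            # post-burn-in generation of the pulse
    p_adm: float        # fraction of offspring gametes drawn from the ghost
    n_ghost: int        # haploid ghost size
    t_div: int          # post-burn-in generation of the main/ghost split

    def __post_init__(self):
        if not (0 <= self.p_adm <= 1):
            raise ValueError("admixture proportion must be in [0,1]")
        if self.t_div > self.gen:
            raise ValueError("ghost divergence must precede the pulse")


@dataclass(frozen=True)
class DemographySchedule:
    """Haploid population-size schedule on a post-burn-in clock.

    The population evolves ``4 * n_anc`` burn-in generations at size
    ``n_anc``, then ``duration`` further generations during which size
    changes (``epochs``: generation -> new haploid size), fixed 100-
    generation bottlenecks and admixture pulses apply.
    """

    n_anc: int = 400
    duration: int = 0
    epochs: tuple[tuple[int, int], ...] = ()
    bottlenecks: tuple[tuple[int, int], ...] = ()   # (start gen, haploid size)
    admixture: tuple[AdmixturePulse, ...] = ()

    def __post_init__(self):
        if self.n_anc < 4:
            raise ValueError("need at least 2 diploids")
        for g, n in self.epochs:
            if g < 0 or n < 4:
                raise ValueError("bad epoch")

    @property
    def burn_in(self) -> int:
        return 4 * self.n_anc

    def size_at(self, gen: int) -> int:
        """Haploid size at post-burn-in generation ``gen`` (gen<0: burn-in)."""
        size = self.n_anc
        for g, n in sorted(self.epochs):
            if gen >= g:
                size = n
        for g, n in self.bottlenecks:
            if g <= gen < g + BOTTLENECK_DURATION:
                size = n
        return size

    def scaled(self, factor: float) -> "DemographySchedule":
        """Scale all times and sizes by ``factor`` (rates untouched)."""
        def t(x):
            return max(int(round(x * factor)), 4)
        return replace(
            self,
            n_anc=t(self.n_anc),
            duration=int(round(self.duration * factor)),
            epochs=tuple((int(round(g * factor)), t(n))
                         for g, n in self.epochs),
            bottlenecks=tuple((int(round(g * factor)), t(n))
                              for g, n in self.bottlenecks),
            admixture=tuple(replace(a, gen=int(round(a.gen * factor)),
                                    n_ghost=t(a.n_ghost),
                                    t_div=int(round(a.t_div * factor)))
                            for a in self.admixture),
        )


@dataclass
class SimOutput:
    """Final full population of one forward run."""

    haplotypes: np.ndarray        # (2N, S) uint8 presence of derived allele
    positions: np.ndarray         # (S,) float bp positions, sorted
    selected: np.ndarray          # (S,) bool, True = in a selected stretch
    arch: GenomeArchitecture
    sel: SelectionParams
    demo: DemographySchedule
    seed: int | None
    n_substitutions: int = 0

    @property
    def n_haploid(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def derived_totals(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int64)

    def dosage_matrix(self, cols: np.ndarray | None = None) -> np.ndarray:
        """(n_sites, n_diploid) derived dosages (haplotype pairs 2i, 2i+1)."""
        h = self.haplotypes if cols is None else self.haplotypes[:, cols]
        return (h[0::2] + h[1::2]).T.astype(np.uint8)


class _Population:
    """Mutable haplotype matrix sharing a global site registry."""

    def __init__(self, haps: np.ndarray):
        self.haps = haps

    def step(self, positions, selected, n_next, s, r, L, rng,
             ext_parent_rows=None, n_ext=0):
        """One Wright–Fisher generation; returns the offspring matrix.

        ``ext_parent_rows``: haplotype matrix of an external (admixing)
        population; the first ``n_ext`` gametes take their parents from it.
        """
        haps = self.haps
        n_par = haps.shape[0] // 2
        S = haps.shape[1]

        # fitness over selected sites
        if s > 0 and selected.any():
            sel_cols = np.flatnonzero(selected)
            dos = (haps[0::2][:, sel_cols].astype(np.int16)
                   + haps[1::2][:, sel_cols])
            het = (dos == 1).sum(axis=1)
            hom = (dos == 2).sum(axis=1)
            logw = het * np.log1p(-s / 2) + hom * np.log1p(-s)
            w = np.exp(logw - logw.max())
            tot = w.sum()
            if not np.isfinite(tot) or tot <= 0:
                raise RuntimeError("population mean fitness collapsed to 0")
            p = w / tot
        else:
            p = np.full(n_par, 1.0 / n_par)

        cum = np.cumsum(p)
        parents = np.searchsorted(cum, rng.random(n_next))
        np.clip(parents, 0, n_par - 1, out=parents)
        child = _recombine(haps, positions, parents, r, L, rng)

        if ext_parent_rows is not None and n_ext > 0:
            # external gametes: same machinery against the ghost matrix
            child_ext = _draw_gametes(ext_parent_rows, positions, n_ext,
                                      r, L, rng)
            return np.concatenate([child_ext, child[n_ext:]], axis=0)
        return child


def _recombine(haps, positions, parents, r, L, rng):
    """Form one gamete per parent index: random start chromatid, then a
    crossover mosaic for the Poisson(r·L) gametes with breakpoints."""
    n_gam = parents.size
    coin = rng.integers(0, 2, size=n_gam)
    child = haps[2 * parents + coin]            # zero-crossover default
    k = rng.poisson(r * L, size=n_gam)
    for g in np.flatnonzero(k):
        pair = haps[2 * parents[g]: 2 * parents[g] + 2]
        if k[g] == 1:                           # common case: one slice swap
            cut = np.searchsorted(positions, rng.uniform(0, L))
            child[g, cut:] = pair[1 - coin[g], cut:]
        else:
            bps = np.sort(rng.uniform(0, L, size=k[g]))
            parity = (coin[g] + np.searchsorted(bps, positions)) % 2
            np.copyto(child[g], np.where(parity == 0, pair[0], pair[1]))
    return child


def _draw_gametes(haps, positions, n_gam, r, L, rng):
    """Neutral gamete draws (uniform parents) from ``haps``."""
    n_par = haps.shape[0] // 2
    parents = rng.integers(0, n_par, size=n_gam)
    return _recombine(haps, positions, parents, r, L, rng)


def simulate(arch: GenomeArchitecture, sel: SelectionParams,
             demo: DemographySchedule, seed: int | None = None) -> SimOutput:
    """Run one forward Wright–Fisher replicate and return the final
    population."""
    rng = np.random.default_rng(seed)
    L = float(arch.length)
    u, r, s = sel.u, sel.r, sel.s

    positions = np.empty(0)
    selected = np.empty(0, dtype=bool)
    haps = np.zeros((demo.n_anc, 0), dtype=np.uint8)
    n_subst = 0

    ghost: np.ndarray | None = None
    pulses = sorted(demo.admixture, key=lambda a: a.gen)
    if len(pulses) > 1:
        raise NotImplementedError("a single admixture pulse is supported")
    pulse = pulses[0] if pulses else None

    total = demo.burn_in + demo.duration
    for gen in range(total):
        t = gen - demo.burn_in              # post-burn-in clock
        n_next = demo.size_at(t) if t >= 0 else demo.n_anc

        # ghost split: copy of the main population resized to n_ghost
        if pulse is not None and t == pulse.t_div:
            pick = rng.choice(haps.shape[0], size=pulse.n_ghost, replace=True)
            ghost = haps[pick].copy()

        pop = _Population(haps)
        if pulse is not None and t == pulse.gen and ghost is not None:
            n_ext = rng.binomial(n_next, pulse.p_adm)
            child = pop.step(positions, selected, n_next, s, r, L, rng,
                             ext_parent_rows=ghost, n_ext=n_ext)
            ghost = None                     # single pulse: ghost retires
        else:
            child = pop.step(positions, selected, n_next, s, r, L, rng)
            if ghost is not None:
                ghost = _draw_gametes(ghost, positions, ghost.shape[0],
                                      r, L, rng)

        # new mutations, infinite sites on continuous positions
        n_new = rng.poisson(u * L * n_next)
        if n_new:
            new_pos = rng.uniform(0, L, size=n_new)
            while np.isin(new_pos, positions).any() or \
                    len(np.unique(new_pos)) != n_new:
                new_pos = rng.uniform(0, L, size=n_new)
            carrier = rng.integers(0, n_next, size=n_new)
            block = np.zeros((n_next, n_new), dtype=np.uint8)
            block[carrier, np.arange(n_new)] = 1
            child = np.concatenate([child, block], axis=1)
            if ghost is not None:
                ghost = np.concatenate(
                    [ghost, np.zeros((ghost.shape[0], n_new), dtype=np.uint8)],
                    axis=1)
            positions = np.concatenate([positions, new_pos])
            selected = np.concatenate([selected, arch.is_selected(new_pos)])
            order = np.argsort(positions)
            positions = positions[order]
            selected = selected[order]
            child = child[:, order]
            if ghost is not None:
                ghost = ghost[:, order]

        # purge fixed/lost sites (fixed deleterious mutations carry no
        # relative fitness information once purged)
        tot_main = child.sum(axis=0, dtype=np.int64)
        if ghost is not None:
            tot_all = tot_main + ghost.sum(axis=0, dtype=np.int64)
            full = child.shape[0] + ghost.shape[0]
        else:
            tot_all, full = tot_main, child.shape[0]
        seg = (tot_all > 0) & (tot_all < full)
        if not seg.all():
            n_subst += int(np.count_nonzero(tot_all == full))
            child = child[:, seg]
            positions = positions[seg]
            selected = selected[seg]
            if ghost is not None:
                ghost = ghost[:, seg]
        if child.shape[1] > MAX_SEGREGATING:
            raise MemoryError(
                f"{child.shape[1]} segregating sites exceeds the guard of "
                f"{MAX_SEGREGATING}; reduce u, L or population size")
        haps = child

    return SimOutput(haps, positions, selected, arch, sel, demo, seed,
                     n_substitutions=n_subst)


def recombination_response_experiment(
        r_values: Sequence[float] = (1e-9, 1e-8, 1e-7, 1e-6),
        s: float = 0.1,
        n_regions: int = 50,
        sel_len: int = 1000,
        neu_len: int = 4000,
        n_anc: int = 400,
        n_replicates: int = 30,
        n_snps: int = 40_000,
        n_project: int = 20,
        seed: int = 0) -> dict:
    """Replicated forward runs across recombination rates (reduced-scale
    re-creation of the BGS dafi-vs-recombination design).

    For each crossover rate, ``n_replicates`` independent runs are simulated,
    summarised by mean DAF̄ᵢ and the projected normalized SFS.  Returns
    ``{"r_values", "dafi" (n_r, n_rep), "eta_mean" (n_r, n_project-1),
    "eta" (n_r, n_rep, n_project-1)}``.
    """
    arch = GenomeArchitecture(n_regions, sel_len, neu_len)
    demo = DemographySchedule(n_anc=n_anc)
    dafi = np.zeros((len(r_values), n_replicates))
    eta = np.zeros((len(r_values), n_replicates, n_project - 1))
    for i, r in enumerate(r_values):
        for rep in range(n_replicates):
            sub_seed = seed + 1000 * i + rep
            sim = simulate(arch, SelectionParams(s=s, u=1.25e-7, r=r),
                           demo, seed=sub_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d, e = summarize(sim, n_snps=n_snps, n_project=n_project,
                                 seed=sub_seed)
            dafi[i, rep] = float(np.mean(d))
            eta[i, rep] = e.xi
    return {"r_values": np.asarray(r_values, dtype=float), "dafi": dafi,
            "eta": eta, "eta_mean": eta.mean(axis=1)}


def sample_snps(out: SimOutput, n_snps: int = 40_000,
                seed: int | None = None) -> np.ndarray:
    """Uniform without-replacement subsample of segregating neutral-stretch
    sites (column indices).  Takes all of them, with a warning, when fewer
    than ``n_snps`` exist."""
    totals = out.derived_totals()
    neutral = np.flatnonzero(~out.selected
                             & (totals > 0) & (totals < out.n_haploid))
    if neutral.size == 0:
        raise ValueError("no segregating neutral sites")
    if neutral.size <= n_snps:
        if neutral.size < n_snps:
            warnings.warn(f"only {neutral.size} segregating neutral sites "
                          f"available (requested {n_snps})")
        return neutral
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(neutral, size=n_snps, replace=False))


def summarize(out: SimOutput, n_snps: int = 40_000, n_project: int = 20,
              seed: int | None = None):
    """Per-individual DAF̄ᵢ over a SNP subsample plus the projected,
    normalized SFS of the full population.

    Returns ``(dafi_values, normalized_projected_sfs)``.
    """
    if n_project > out.n_haploid:
        raise ValueError("cannot project above the population size")
    cols = sample_snps(out, n_snps, seed)
    dos = out.dosage_matrix(cols)                      # (sites, n_diploid)
    n_i = dos.sum(axis=0, dtype=np.int64)
    dafi = n_i / (2.0 * dos.shape[0])

    totals = out.derived_totals()[cols]
    pairs = np.stack([np.full(cols.size, out.n_haploid), totals], axis=1)
    proj = sfs_toolkit.project_sfs(pairs, n_project)
    return dafi, sfs_toolkit.normalize_sfs(proj)
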