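"""Synthetic datasets with known ground truth.

Generates multi-population polarized genotype data from a hand-rolled
structured Kingman coalescent with piecewise-constant population sizes and
population merges, then layers on the two signals the analysis is designed
to detect:

- background selection, emulated as a recombination-dependent rescaling of
  the *deep* (ancestral) effective size: shrinking the deep epochs shortens
  a genealogy's interior branches relative to its external ones, producing
  the singleton excess and reduced DAF̄ᵢ that BGS causes, with strength
  decreasing in the local recombination rate;
- gBGC, emulated as genic directional selection with scaled coefficient
  γ(rate): derived frequencies at WS sites are drawn from Wright's
  stationary density with +γ, SW with −γ, WW/SS sites stay neutral.

Time is measured in units of 2·N_ref generations, so the pairwise
coalescence rate inside a population of relative size σ is 1/σ and a
sample of n haploids from a constant population has E[T_MRCA] = 2(1−1/n)
and E[T_total] = 2·Σ_{i<n} 1/i.  Loci are unlinked (independent
genealogies); within-locus recombination is not simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .io_formats import Individual, SnpRecord, SnpTable
from .snp_annotation import classify_mutation

# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Piecewise-constant size history: (start_time, relative_size) epochs,
    times backwards from the present, first epoch starting at 0."""

    name: str
    epochs: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    def __post_init__(self):
        if self.epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        times = [t for t, _ in self.epochs]
        if times != sorted(times):
            raise ValueError("epochs must be time-ordered")
        if any(s <= 0 for _, s in self.epochs):
            raise ValueError("sizes must be positive")

    def size_at(self, t: float) -> float:
        size = self.epochs[0][1]
        for start, s in self.epochs:
            if t >= start:
                size = s
        return size

    def boundaries_after(self, t: float) -> list[float]:
        return [start for start, _ in self.epochs if start > t]


@dataclass(frozen=True)
class SharedDemography:
    """Populations plus merge events (time, source, dest) joining source's
    lineages into dest — a shared global tree over distinct histories."""

    populations: tuple[PopulationModel, ...]
    merges: tuple[tuple[float, str, str], ...] = ()

    def pop(self, name: str) -> PopulationModel:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def deep_rescaled(self, multiplier: float,
                      deep_time: float | None = None) -> "SharedDemography":
        """Multiply sizes of epochs starting at/after ``deep_time``.

        Default ``deep_time``: the latest merge time (i.e. the ancestral
        population), or 0 for a single unstructured population (whole
        history).  This is the BGS emulation knob: multiplier < 1 shortens
        deep coalescence, lowering E(DAF̄ᵢ).
        """
        if deep_time is None:
            deep_time = max((t for t, _, _ in self.merges), default=0.0)
        pops = []
        for p in self.populations:
            epochs = []
            for start, size in p.epochs:
                epochs.append((start,
                               size * multiplier if start >= deep_time
                               else size))
            if deep_time > 0 and all(start < deep_time
                                     for start, _ in p.epochs):
                # ensure the deep regime actually begins at deep_time
                epochs.append((deep_time, p.size_at(deep_time) * multiplier))
            pops.append(PopulationModel(p.name, tuple(epochs)))
        return SharedDemography(tuple(pops), self.merges)


def constant_demography(size: float = 1.0,
                        name: str = "pop0") -> SharedDemography:
    return SharedDemography((PopulationModel(name, ((0.0, size),)),))


def two_population_bottleneck(bottleneck_factor: float = 0.1,
                              bottleneck_end: float = 0.2,
                              split_time: float = 0.5) -> SharedDemography:
    """Two populations with shared ancestry: 'constant' of size 1, and
    'bottleneck' at size/``bottleneck_factor``... i.e. reduced 10× (default)
    from the present back to ``bottleneck_end``; both merge into the
    constant-size ancestor at ``split_time``."""
    popA = PopulationModel("constant", ((0.0, 1.0),))
    popB = PopulationModel("bottleneck", ((0.0, bottleneck_factor),
                                          (bottleneck_end, 1.0)))
    return SharedDemography((popA, popB),
                            ((split_time, "bottleneck", "constant"),))


# ---------------------------------------------------------------------------
# Structured coalescent
# ---------------------------------------------------------------------------

@dataclass
class CoalescentTree:
    """Genealogy as a branch list: (descendant leaf indices, branch length).

    ``t_global`` is the TMRCA, ``t_tot`` the total branch length, both in
    units of 2·N_ref generations.
    """

    n_leaves: int
    branches: list[tuple[np.ndarray, float]]
    t_global: float
    leaf_populations: np.ndarray

    @property
    def t_tot(self) -> float:
        return float(sum(l for _, l in self.branches))


def simulate_genealogy(samples: dict[str, int],
                       demography: SharedDemography,
                       ne_multiplier: float = 1.0,
                       rng: np.random.Generator | None = None) -> CoalescentTree:
    """Simulate one structured-coalescent genealogy.

    ``samples`` maps population name to its number of *haploid* lineages.
    ``ne_multiplier`` rescales every epoch of every population (a pure time
    rescaling for a constant single population).  Populations with samples
    must exist in the demography; any lineage must eventually reach a common
    population through the merge events.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0 < ne_multiplier):
        raise ValueError("ne_multiplier must be positive")
    total = sum(samples.values())
    if total < 2:
        raise ValueError("need at least 2 haploid lineages")

    # leaf numbering: populations in demography order, lineages consecutive
    lineages: dict[str, list[tuple[np.ndarray, float]]] = {}
    leaf_pop = []
    leaf = 0
    for p in demography.populations:
        k = samples.get(p.name, 0)
        lineages[p.name] = [(np.array([leaf + j]), 0.0) for j in range(k)]
        leaf_pop.extend([p.name] * k)
        leaf += k
    unknown = set(samples) - {p.name for p in demography.populations}
    if unknown:
        raise ValueError(f"samples reference unknown population(s) {unknown}")

    merges = sorted(demography.merges)
    branches: list[tuple[np.ndarray, float]] = []
    t = 0.0
    mi = 0
    while sum(len(v) for v in lineages.values()) > 1:
        # candidate waiting times within the current constant-size stretch
        next_merge = merges[mi][0] if mi < len(merges) else math.inf
        boundary = next_merge
        rates = {}
        for p in demography.populations:
            k = len(lineages[p.name])
            for bt in p.boundaries_after(t):
                boundary = min(boundary, bt)
            if k >= 2:
                sigma = p.size_at(t) * ne_multiplier
                rates[p.name] = k * (k - 1) / 2.0 / sigma
        if not rates:
            if boundary is math.inf:
                raise RuntimeError(
                    "lineages can never coalesce: isolated populations "
                    "with no merge event")
            t = boundary
            while mi < len(merges) and merges[mi][0] <= t:
                _, src, dst = merges[mi]
                lineages[dst].extend(lineages.pop(src, []))
                lineages[src] = []
                mi += 1
            continue
        total_rate = sum(rates.values())
        wait = rng.exponential(1.0 / total_rate)
        if t + wait >= boundary:
            t = boundary
            while mi < len(merges) and merges[mi][0] <= t:
                _, src, dst = merges[mi]
                lineages[dst].extend(lineages.pop(src, []))
                lineages[src] = []
                mi += 1
            continue
        t += wait
        # pick the population, then a uniform pair within it
        u = rng.uniform(0, total_rate)
        acc = 0.0
        for name, rate in rates.items():
            acc += rate
            if u < acc:
                pop = name
                break
        group = lineages[pop]
        i, j = rng.choice(len(group), size=2, replace=False)
        (la, ta), (lb, tb) = group[i], group[j]
        branches.append((la, t - ta))
        branches.append((lb, t - tb))
        merged = (np.concatenate([la, lb]), t)
        group[:] = [g for idx, g in enumerate(group) if idx not in (i, j)]
        group.append(merged)
    return CoalescentTree(total, branches, t, np.array(leaf_pop, dtype=object))


# ---------------------------------------------------------------------------
# Mutation dropping (neutral and gBGC-biased)
# ---------------------------------------------------------------------------

#: default ordered-pair mutation probabilities: transitions twice as likely
#: as transversions
def default_class_probs() -> dict[tuple[str, str], float]:
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    probs = {}
    for a in "ACGT":
        for d in "ACGT":
            if a != d:
                probs[(a, d)] = 2.0 if (a, d) in transitions else 1.0
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}


def wright_biased_pmf(gamma: float, m: int) -> np.ndarray:
    """Sample-frequency pmf (classes 1..m-1) of Wright's stationary density
    under genic selection with scaled coefficient γ, midpoint-discretized:

        f(x) ∝ (1 − e^{−γ(1−x)}) / ((1 − e^{−γ}) · x(1−x)) ,

    reducing to the neutral 1/x shape as γ → 0.
    """
    x = np.arange(1, m) / m
    if abs(gamma) < 1e-9:
        w = 1.0 / x
    else:
        w = (1.0 - np.exp(-gamma * (1.0 - x))) / (
            (1.0 - np.exp(-gamma)) * x * (1.0 - x))
    return w / w.sum()


@dataclass
class SiteRecord:
    carriers: np.ndarray        # haploid leaf indices carrying the derived allele
    ancestral: str
    derived: str
    mclass: str
    gamma: float


def drop_mutations(tree: CoalescentTree, theta: float,
                   class_probs: dict[tuple[str, str], float] | None = None,
                   gamma: float = 0.0,
                   rng: np.random.Generator | None = None) -> list[SiteRecord]:
    """Place mutations on a genealogy and label them with mutation types.

    Neutral sites fall on branches with Poisson(θ·length/2) counts and are
    carried by the leaves below.  Sites of a gBGC-affected class (γ≠0 for
    WS, −γ for SW) instead draw their derived count from the biased
    stationary pmf and their carriers uniformly (hypergeometric sampling of
    leaves), overriding the tree placement — the directional transmission
    bias, not the genealogy, then controls their frequency.
    """
    if rng is None:
        rng = np.random.default_rng()
    if class_probs is None:
        class_probs = default_class_probs()
    pairs = list(class_probs)
    pvec = np.array([class_probs[p] for p in pairs])
    classes = np.array([classify_mutation(a, d) for a, d in pairs],
                       dtype=object)
    lengths = np.array([l for _, l in tree.branches])
    counts = rng.poisson(theta * lengths / 2.0)
    k_total = int(counts.sum())
    if k_total == 0:
        return []
    m = tree.n_leaves
    branch_of = np.repeat(np.arange(len(counts)), counts)
    pair_idx = rng.choice(len(pairs), size=k_total, p=pvec)

    pmf_cache: dict[float, np.ndarray] = {}
    sites: list[SiteRecord] = []
    for bi, pi in zip(branch_of, pair_idx):
        anc, der = pairs[pi]
        mclass = classes[pi]
        g = {"WS": gamma, "SW": -gamma, "WWSS": 0.0}[mclass]
        if abs(g) < 1e-12:
            carriers = tree.branches[bi][0]
        else:
            if g not in pmf_cache:
                pmf_cache[g] = wright_biased_pmf(g, m)
            i = 1 + rng.choice(m - 1, p=pmf_cache[g])
            carriers = rng.choice(m, size=i, replace=False)
        sites.append(SiteRecord(np.asarray(carriers), anc, der, mclass, g))
    return sites


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def ramp_profile(lo: float = 0.5, hi: float = 1.0, rr_max: float = 1.5):
    """BGS strength profile: deep-size multiplier rising linearly from
    ``lo`` at rate 0 to ``hi`` at ``rr_max`` cM/Mb, flat above (no BGS)."""
    def f(rate):
        return lo + (hi - lo) * min(rate, rr_max) / rr_max
    return f


def threshold_gamma(gamma: float = 3.0, rr_min: float = 1.5):
    """gBGC profile: coefficient γ above ``rr_min`` cM/Mb, 0 below."""
    def f(rate):
        return gamma if rate >= rr_min else 0.0
    return f


@dataclass
class SyntheticConfig:
    n_loci: int = 2000
    samples: dict[str, int] = field(
        default_factory=lambda: {"constant": 10, "bottleneck": 10})  # diploids
    demography: SharedDemography = field(
        default_factory=two_population_bottleneck)
    theta: float = 4.0
    rr_log10_range: tuple[float, float] = (-1.0, 1.3)    # cM/Mb, log-uniform
    bgs_profile: Callable[[float], float] | None = None   # rate -> multiplier
    gbgc_gamma: Callable[[float], float] | None = None    # rate -> γ
    class_probs: dict[tuple[str, str], float] = field(
        default_factory=default_class_probs)
    fraction_transcribed: float = 0.4
    seed: int | None = None

    def __post_init__(self):
        if self.n_loci < 1 or self.theta <= 0:
            raise ValueError("n_loci and theta must be positive")
        z = sum(self.class_probs.values())
        if abs(z - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        names = {p.name for p in self.demography.populations}
        if not set(self.samples) <= names:
            raise ValueError("samples reference unknown populations")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its per-site ground truth."""

    config: SyntheticConfig
    individuals: list[Individual]
    chrom: str
    positions: np.ndarray          # (S,) 1-based
    dosages: np.ndarray            # (S, n_individuals) uint8
    ancestral: np.ndarray          # (S,) bases
    derived: np.ndarray
    mclass: np.ndarray
    rr: np.ndarray                 # per-site rate (cM/Mb)
    locus: np.ndarray              # per-site locus index
    truth: "pd.DataFrame"          # per-locus truth
    locus_rates: np.ndarray
    slab: int

    def to_snp_table(self) -> SnpTable:
        recs = [SnpRecord(self.chrom, int(p), a, d, dos)
                for p, a, d, dos in zip(self.positions, self.ancestral,
                                        self.derived, self.dosages)]
        return SnpTable(recs, self.individuals)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset in memory (no files); see :func:`generate_dataset`
    for the on-disk form ingestible by the io layer."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    hap_samples = {k: 2 * v for k, v in config.samples.items()}
    n_ind = sum(config.samples.values())
    individuals = []
    for p in config.demography.populations:
        for j in range(config.samples.get(p.name, 0)):
            individuals.append(Individual(f"{p.name}_{j}", p.name, p.name))

    lo, hi = config.rr_log10_range
    locus_rates = 10 ** rng.uniform(lo, hi, size=config.n_loci)

    pos_l, dos_l, anc_l, der_l, cls_l, rr_l, loc_l = [], [], [], [], [], [], []
    truth_rows = []
    max_sites = 0
    per_locus_sites: list[list[SiteRecord]] = []
    for ell in range(config.n_loci):
        rate = float(locus_rates[ell])
        mult = config.bgs_profile(rate) if config.bgs_profile else 1.0
        demo = (config.demography.deep_rescaled(mult)
                if config.bgs_profile else config.demography)
        gamma = config.gbgc_gamma(rate) if config.gbgc_gamma else 0.0
        tree = simulate_genealogy(hap_samples, demo, rng=rng)
        sites = drop_mutations(tree, config.theta, config.class_probs,
                               gamma, rng)
        # keep polymorphic-in-sample sites only
        sites = [s for s in sites if 0 < len(s.carriers) < tree.n_leaves]
        per_locus_sites.append(sites)
        max_sites = max(max_sites, len(sites))
        truth_rows.append({"locus": ell, "rate_cMMb": rate,
                           "ne_multiplier": mult, "gamma": gamma,
                           "t_global": tree.t_global, "t_tot": tree.t_tot,
                           "n_sites": len(sites)})

    slab = 2 * max_sites + 10
    for ell, sites in enumerate(per_locus_sites):
        start = ell * slab + 1
        for j, s in enumerate(sites):
            pos = start + 2 + 2 * j     # keeps >=1 background bp around sites
            dos = np.zeros(2 * n_ind, dtype=np.uint8)
            dos[s.carriers] = 1
            dos = dos[0::2] + dos[1::2]
            pos_l.append(pos)
            dos_l.append(dos)
            anc_l.append(s.ancestral)
            der_l.append(s.derived)
            cls_l.append(s.mclass)
            rr_l.append(locus_rates[ell])
            loc_l.append(ell)

    return SyntheticDataset(
        config=config, individuals=individuals, chrom="chr1",
        positions=np.array(pos_l, dtype=np.int64),
        dosages=np.array(dos_l, dtype=np.uint8).reshape(len(pos_l), n_ind),
        ancestral=np.array(anc_l, dtype=object),
        derived=np.array(der_l, dtype=object),
        mclass=np.array(cls_l, dtype=object),
        rr=np.array(rr_l, dtype=float),
        locus=np.array(loc_l, dtype=np.int64),
        truth=pd.DataFrame(truth_rows),
        locus_rates=locus_rates, slab=slab)


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate a dataset and write VCF + ancestral FASTA + reference FASTA
    + recombination map + annotation BEDs + truth TSV.

    The emitted files pass the io layer's filter cascade without unexpected
    losses (no CpG contexts, no missing genotypes, all sites polarizable).
    Returns a dict of output paths plus the in-memory dataset.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate(config)
    rng = np.random.default_rng(None if config.seed is None
                                else config.seed + 1)

    genome_len = config.n_loci * ds.slab + ds.slab

    # reference/ancestral FASTA: background 'A', ancestral base at each site
    seq = np.full(genome_len, b"A", dtype="S1")
    for p, a in zip(ds.positions, ds.ancestral):
        seq[p - 1] = a.encode()
    fasta = out_dir / "ancestral.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{ds.chrom}\n")
        raw = b"".join(seq.tolist()).decode()
        for i in range(0, len(raw), 80):
            fh.write(raw[i: i + 80] + "\n")

    vcf = out_dir / "sites.vcf"
    table = ds.to_snp_table()
    from .io_formats import write_vcf
    write_vcf(table, vcf)

    # map: one anchor per locus slab plus a closing anchor
    gmap = out_dir / "genetic_map.txt"
    with open(gmap, "w") as fh:
        fh.write("chr\tposition\trate_cMMb\tmap_cM\n")
        cum = 0.0
        for ell in range(config.n_loci):
            start = ell * ds.slab + 1
            fh.write(f"{ds.chrom}\t{start}\t{ds.locus_rates[ell]:.6f}\t{cum:.8f}\n")
            cum += ds.locus_rates[ell] * ds.slab / 1e6
        fh.write(f"{ds.chrom}\t{config.n_loci * ds.slab + 1}\t0.0\t{cum:.8f}\n")

    # annotations: random loci transcribed; first quarter of each
    # transcribed slab "exonic"; conserved = a sub-stretch of exons
    tr_bed = out_dir / "transcribed.bed"
    ex_bed = out_dir / "exons.bed"
    cons_bed = out_dir / "conserved.bed"
    tr_loci = rng.random(config.n_loci) < config.fraction_transcribed
    with open(tr_bed, "w") as tf, open(ex_bed, "w") as ef, \
            open(cons_bed, "w") as cf:
        for ell in np.flatnonzero(tr_loci):
            s0 = int(ell) * ds.slab          # 0-based BED start
            tf.write(f"{ds.chrom}\t{s0}\t{s0 + ds.slab}\n")
            ef.write(f"{ds.chrom}\t{s0}\t{s0 + max(ds.slab // 4, 1)}\n")
            cf.write(f"{ds.chrom}\t{s0}\t{s0 + max(ds.slab // 8, 1)}\n")

    truth_tsv = out_dir / "truth.tsv"
    ds.truth.to_csv(truth_tsv, sep="\t", index=False)
    with open(out_dir / "config.json", "w") as fh:
        json.dump({"n_loci": config.n_loci, "samples": config.samples,
                   "theta": config.theta, "seed": config.seed,
                   "rr_log10_range": list(config.rr_log10_range),
                   "slab": ds.slab}, fh, indent=2)

    return {"dataset": ds, "vcf": vcf, "ancestral_fasta": fasta,
            "reference_fasta": fasta, "map": gmap, "transcribed": tr_bed,
            "exons": ex_bed, "conserved": cons_bed, "truth": truth_tsv}
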