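"""SNP-level annotation: gBGC mutation classes, recombination binning,
feature distances, hotspot detection and the neutral-SNP filter.

GC-biased gene conversion favours "strong" (S: C/G) over "weak" (W: A/T)
alleles in W/S heterozygotes, so polarized SNPs split into three classes:
WS (derived allele favoured), SW (derived allele disfavoured) and WW+SS
(unaffected).  Background selection leaves WW+SS sites in high-recombination
regions as the best candidates for neutrally evolving variation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (MISSING, IntervalSet, RecombinationMap, SnpTable,
                         is_missing)

logger = logging.getLogger(__name__)

WEAK = frozenset("AT")
STRONG = frozenset("CG")

#: default neutrality threshold on the local recombination rate (cM/Mb)
NEUTRAL_RR_MIN = 1.5
#: hotspot definition (cM/Mb), strict inequality
HOTSPOT_RR = 10.0


def classify_mutation(ancestral: str, derived: str) -> str:
    """Classify a polarized mutation for gBGC: 'WS', 'SW' or 'WWSS'.

    W (weak) = A/T, S (strong) = C/G.  WS mutations have their derived state
    favoured by gBGC, SW their ancestral state; W<->W and C<->G changes are
    unaffected and pooled as WWSS.
    """
    a, d = ancestral.upper(), derived.upper()
    if a not in WEAK | STRONG or d not in WEAK | STRONG:
        raise ValueError(f"non-ACGT base in ({ancestral},{derived})")
    if a == d:
        raise ValueError("ancestral and derived bases are identical")
    if a in WEAK and d in STRONG:
        return "WS"
    if a in STRONG and d in WEAK:
        return "SW"
    return "WWSS"


@dataclass
class AnnotatedSnpTable(SnpTable):
    """SnpTable plus per-record annotation arrays (aligned with records).

    Annotation keys: 'class' (WS/SW/WWSS), 'pair' (12-way 'A>G' label),
    'rr_cMMb', 'bin' (1..B, 0 = unbinned), 'in_tr', and the dist_* columns.
    Missing numeric values are NaN.
    """

    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: SnpTable) -> "AnnotatedSnpTable":
        t = cls(list(table.records), list(table.individuals),
                dict(table.filter_log))
        n = len(t.records)
        t.annotations = {
            "class": np.array([classify_mutation(r.ancestral, r.derived)
                               for r in t.records], dtype=object),
            "pair": np.array([f"{r.ancestral}>{r.derived}"
                              for r in t.records], dtype=object),
            "rr_cMMb": np.full(n, MISSING),
            "bin": np.zeros(n, dtype=np.int64),
        }
        return t

    def subset(self, keep) -> "AnnotatedSnpTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        out = AnnotatedSnpTable([self.records[i] for i in keep],
                                self.individuals, dict(self.filter_log))
        out.annotations = {k: v[keep] for k, v in self.annotations.items()}
        return out

    # convenience accessors -------------------------------------------------
    @property
    def mutation_class(self) -> np.ndarray:
        return self.annotations["class"]

    @property
    def rr(self) -> np.ndarray:
        return self.annotations["rr_cMMb"]

    @property
    def bins(self) -> np.ndarray:
        return self.annotations["bin"]


def annotate_rates(table: AnnotatedSnpTable, rmap: RecombinationMap) -> None:
    """Attach the local recombination rate (cM/Mb) to every record."""
    rr = np.array([rmap.rate_at(r.chrom, r.pos) for r in table.records])
    table.annotations["rr_cMMb"] = rr
    n_missing = int(np.isnan(rr).sum())
    if n_missing:
        logger.info("%d/%d SNPs without recombination-rate information",
                    n_missing, len(table))


def assign_recombination_bins(table: AnnotatedSnpTable,
                              n_bins: int = 20) -> "pd.DataFrame":
    """Split rate-annotated SNPs into ``n_bins`` equal-size rate bins.

    SNPs with a defined rate are ranked by (rate, chrom, pos) — the
    positional tie-break makes the split deterministic — and cut into
    contiguous groups whose sizes differ by at most one.  Bin indices
    (1..n_bins) increase with rate; SNPs without rate stay unbinned (0).

    Returns a per-bin summary frame (bin, n_snps, mean_rr).
    """
    import pandas as pd

    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rr = table.annotations["rr_cMMb"]
    defined = np.flatnonzero(~np.isnan(rr))
    if len(defined) < n_bins:
        raise ValueError(
            f"only {len(defined)} SNPs with rate information, need >= {n_bins}")
    keys = sorted(defined,
                  key=lambda i: (rr[i], table.records[i].chrom,
                                 table.records[i].pos))
    sizes = np.full(n_bins, len(keys) // n_bins, dtype=int)
    sizes[: len(keys) % n_bins] += 1
    bins = np.zeros(len(table), dtype=np.int64)
    start = 0
    summary = []
    for b, sz in enumerate(sizes, start=1):
        members = keys[start: start + sz]
        bins[members] = b
        summary.append({"bin": b, "n_snps": sz,
                        "mean_rr": float(np.mean(rr[members]))})
        start += sz
    table.annotations["bin"] = bins
    return pd.DataFrame(summary)


def _boundary_points(features: IntervalSet, chrom: str) -> np.ndarray:
    return features.intervals(chrom)


def distance_to_nearest(table: AnnotatedSnpTable, features: IntervalSet,
                        rmap: RecombinationMap | None = None,
                        units: str = "bp") -> np.ndarray:
    """Per-SNP distance to the nearest feature interval, in bp or cM.

    0 when the SNP lies inside a feature; otherwise the minimum over feature
    boundaries.  Distances on half-open intervals: a SNP at a feature's end
    coordinate is outside it, at distance 0+ from the last included bp.
    NaN when the map lacks the SNP (cM units) or the chromosome has no
    features.
    """
    if units not in ("bp", "cM"):
        raise ValueError("units must be 'bp' or 'cM'")
    if units == "cM" and rmap is None:
        raise ValueError("cM distances need a recombination map")
    n = len(table)
    out = np.full(n, MISSING)
    if len(features) == 0:
        warnings.warn("empty feature set: all distances missing")
        return out
    for i, r in enumerate(table.records):
        ivs = features.intervals(r.chrom)
        if not len(ivs):
            continue
        j = int(np.searchsorted(ivs[:, 0], r.pos, side="right")) - 1
        if j >= 0 and r.pos < ivs[j, 1]:
            out[i] = 0.0
            continue
        # nearest included bp among candidate neighbours
        cand = []
        if j >= 0:
            cand.append(ivs[j, 1] - 1)          # last bp of left feature
        if j + 1 < len(ivs):
            cand.append(ivs[j + 1, 0])          # first bp of right feature
        if units == "bp":
            out[i] = min(abs(r.pos - c) for c in cand)
        else:
            ds = [rmap.genetic_distance(r.chrom, r.pos, int(c)) for c in cand]
            ds = [d for d in ds if not is_missing(d)]
            out[i] = min(ds) if ds else MISSING
    return out


def detect_hotspots(rmap: RecombinationMap,
                    threshold: float = HOTSPOT_RR) -> IntervalSet:
    """Map intervals with rate strictly above ``threshold``, merged."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom in rmap.chroms:
        for start, end, rate, _ in rmap.intervals(chrom):
            if rate > threshold and end > start:
                ivs.setdefault(chrom, []).append((start, end))
    return IntervalSet(ivs, label="hotspot")


def neutral_filter(table: AnnotatedSnpTable,
                   rr_min: float = NEUTRAL_RR_MIN) -> AnnotatedSnpTable:
    """The neutral-SNP filter: WW+SS sites with recombination rate >= rr_min.

    These sites are unaffected by gBGC by construction and, above the
    threshold, background selection is absent or strongly reduced.  The
    retained fraction is logged.
    """
    rr = table.annotations["rr_cMMb"]
    cls = table.annotations["class"]
    with np.errstate(invalid="ignore"):
        keep = (cls == "WWSS") & ~np.isnan(rr) & (rr >= rr_min)
    if len(table) and not keep.any():
        warnings.warn("neutral filter retained no sites")
    frac = float(keep.sum()) / len(table) if len(table) else math.nan
    logger.info("neutral filter retained %d/%d sites (%.2f%%)",
                int(keep.sum()), len(table), 100 * frac)
    out = table.subset(keep)
    out.neutral_fraction = frac
    return out
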