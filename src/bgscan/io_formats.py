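"""Input/output layer: polarized SNP tables, recombination maps, interval sets.

All genomic positions are handled 1-based internally.  VCF input is 1-based
(native), BED input is 0-based half-open and converted on read, genetic-map
positions are 1-based with half-open rate intervals.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: marker for "no information" on floats (recombination rate, distances)
MISSING = math.nan


def is_missing(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


# ---------------------------------------------------------------------------
# Core record types
# ---------------------------------------------------------------------------

@dataclass
class SnpRecord:
    """A polarized diallelic SNP with per-individual derived-allele dosages."""

    chrom: str
    pos: int                      # 1-based bp
    ancestral: str
    derived: str
    dosages: np.ndarray           # uint8, one entry in {0,1,2} per diploid

    def __post_init__(self) -> None:
        if self.ancestral not in VALID_BASES or self.derived not in VALID_BASES:
            raise ValueError(
                f"bases must be in ACGT, got {self.ancestral}>{self.derived}")
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived bases are identical")
        self.dosages = np.asarray(self.dosages, dtype=np.uint8)
        if self.dosages.size and self.dosages.max() > 2:
            raise ValueError("dosage outside {0,1,2}")

    @property
    def derived_total(self) -> int:
        return int(self.dosages.sum())

    @property
    def monomorphic_in_sample(self) -> bool:
        t = self.derived_total
        return t == 0 or t == 2 * len(self.dosages)

    def flipped(self) -> "SnpRecord":
        """Swap ancestral/derived polarity (dosages become 2 - dosage)."""
        return SnpRecord(self.chrom, self.pos, self.derived, self.ancestral,
                         2 - self.dosages.astype(np.int16))


@dataclass
class Individual:
    sample_id: str
    population: str = "pop0"
    region: str = "region0"


@dataclass
class SnpTable:
    """Sorted collection of polarized SNPs plus sample metadata.

    ``filter_log`` counts records removed per filtering rule; the counts plus
    the retained records always sum to the number of input records.
    """

    records: list[SnpRecord]
    individuals: list[Individual]
    filter_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.chrom, r.pos) for r in self.records]
        if keys != sorted(keys):
            self.records.sort(key=lambda r: (r.chrom, r.pos))
            keys = sorted(keys)
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) in SnpTable")
        n = len(self.individuals)
        for r in self.records:
            if len(r.dosages) != n:
                raise ValueError(
                    f"{r.chrom}:{r.pos} has {len(r.dosages)} dosages, "
                    f"expected {n}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_individuals) uint8 matrix of derived dosages."""
        if not self.records:
            return np.zeros((0, self.n_individuals), dtype=np.uint8)
        return np.stack([r.dosages for r in self.records])

    def subset(self, keep: Sequence[int] | np.ndarray) -> "SnpTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        recs = [self.records[i] for i in keep]
        return SnpTable(recs, self.individuals, dict(self.filter_log))


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

class RecombinationMap:
    """Piecewise-constant recombination map.

    Built from HapMap-style anchors ``(pos, rate cM/Mb, cum cM)``; the rate
    attached to an anchor applies on ``[pos, next_pos)``.  Queries outside the
    anchored extent return NaN ("no rate information").
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # anchors: chrom -> (positions, rates, cums); last anchor closes the map
        self._anchors = {}
        for chrom, (pos, rate, cum) in anchors.items():
            pos = np.asarray(pos, dtype=np.int64)
            rate = np.asarray(rate, dtype=float)
            cum = np.asarray(cum, dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"unsorted map positions on {chrom}")
            if np.any(rate < 0):
                raise ValueError(f"negative recombination rate on {chrom}")
            self._anchors[chrom] = (pos, rate, cum)

    @property
    def chroms(self) -> list[str]:
        return list(self._anchors)

    def intervals(self, chrom: str) -> list[tuple[int, int, float, float]]:
        """(start, end, rate, cum_at_start) half-open intervals."""
        pos, rate, cum = self._anchors[chrom]
        out = []
        for i in range(len(pos) - 1):
            out.append((int(pos[i]), int(pos[i + 1]), float(rate[i]), float(cum[i])))
        if len(pos) == 1:
            # single anchor: open-ended interval at the anchored rate
            out.append((int(pos[0]), np.iinfo(np.int64).max, float(rate[0]),
                        float(cum[0])))
        return out

    def rate_at(self, chrom: str, pos: int) -> float:
        """Local rate (cM/Mb) at ``pos``, NaN if off-map."""
        if chrom not in self._anchors:
            return MISSING
        p, r, _ = self._anchors[chrom]
        if len(p) == 1:
            return float(r[0]) if pos >= p[0] else MISSING
        i = int(np.searchsorted(p, pos, side="right")) - 1
        if i < 0 or i >= len(p) - 1:
            return MISSING
        return float(r[i])

    def cum_at(self, chrom: str, pos: int) -> float:
        """Cumulative genetic position (cM) at ``pos``, NaN if off-map."""
        if chrom not in self._anchors:
            return MISSING
        p, r, c = self._anchors[chrom]
        if len(p) == 1:
            if pos < p[0]:
                return MISSING
            return float(c[0] + r[0] * (pos - p[0]) / 1e6)
        i = int(np.searchsorted(p, pos, side="right")) - 1
        if i < 0:
            return MISSING
        if i >= len(p) - 1:
            if pos == p[-1]:
                return float(c[-1])
            return MISSING
        return float(c[i] + r[i] * (pos - p[i]) / 1e6)

    def genetic_distance(self, chrom: str, pos1: int, pos2: int) -> float:
        """|cum(pos2) - cum(pos1)| in cM, NaN if either position is off-map."""
        a = self.cum_at(chrom, pos1)
        b = self.cum_at(chrom, pos2)
        if is_missing(a) or is_missing(b):
            return MISSING
        return abs(b - a)

    def check_consistency(self, tol: float = 1e-6) -> None:
        for chrom, (p, r, c) in self._anchors.items():
            expect = c[:-1] + r[:-1] * np.diff(p) / 1e6
            if len(expect) and np.max(np.abs(expect - c[1:])) > tol:
                raise ValueError(f"map cumulative cM inconsistent on {chrom}")


def read_recombination_map(path: str | Path) -> RecombinationMap:
    """Read a HapMap-style genetic map (chrom, pos bp, rate cM/Mb, map cM).

    A header line is tolerated.  Cumulative cM is recomputed from rates and
    positions so the map's internal consistency invariant holds by
    construction.
    """
    anchors: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                pos = int(parts[1])
                rate = float(parts[2])
            except ValueError:
                if ln == 1:     # header
                    continue
                raise ValueError(f"malformed map line {ln}: {line.strip()!r}")
            chrom = parts[0]
            anchors.setdefault(chrom, []).append((pos, rate))
    if not anchors:
        raise ValueError("empty recombination map")
    built = {}
    for chrom, rows in anchors.items():
        pos = np.array([p for p, _ in rows], dtype=np.int64)
        rate = np.array([r for _, r in rows], dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted map on {chrom}")
        if np.any(rate < 0):
            raise ValueError(f"negative rate on {chrom}")
        cum = np.zeros(len(pos))
        if len(pos) > 1:
            cum[1:] = np.cumsum(rate[:-1] * np.diff(pos) / 1e6)
        built[chrom] = (pos, rate, cum)
    return RecombinationMap(built)


# ---------------------------------------------------------------------------
# Interval sets (BED)
# ---------------------------------------------------------------------------

class IntervalSet:
    """Per-chromosome sorted, merged half-open intervals (internally 1-based).

    ``start`` is the first included bp, ``end`` the first excluded bp, both
    1-based; a BED line ``chr1 10 20`` becomes [11, 21).
    """

    def __init__(self, intervals: dict[str, Iterable[tuple[int, int]]],
                 label: str = ""):
        self.label = label
        self._ivs: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted((int(s), int(e)) for s, e in ivs)
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"empty interval [{s},{e}) on {chrom}")
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._ivs[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)

    @property
    def chroms(self) -> list[str]:
        return list(self._ivs)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.zeros((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self._ivs.get(chrom)
        if ivs is None or not len(ivs):
            return False
        i = bisect_right(ivs[:, 0].tolist(), pos) - 1
        return i >= 0 and pos < ivs[i, 1]

    def total_span(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self._ivs.values()))


def read_intervals(path: str | Path, label: str = "") -> IntervalSet:
    """Read a BED3 file into an IntervalSet (0-based half-open on disk)."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"empty interval at line {ln} of {path}")
            ivs.setdefault(chrom, []).append((start + 1, end + 1))
    return IntervalSet(ivs, label=label)


def write_intervals(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in ivset.chroms:
            for s, e in ivset.intervals(chrom):
                fh.write(f"{chrom}\t{s - 1}\t{e - 1}\n")


# ---------------------------------------------------------------------------
# Ancestral state sources
# ---------------------------------------------------------------------------

class AncestralSource:
    """Per-position ancestral base lookup, from a FASTA or a VCF INFO tag."""

    def __init__(self, fasta_path: str | Path | None = None,
                 info_tag: str | None = None):
        if fasta_path is None and info_tag is None:
            raise ValueError("need a FASTA path or an INFO tag name")
        self.info_tag = info_tag
        self._fa = None
        if fasta_path is not None:
            from pyfaidx import Fasta
            self._fa = Fasta(str(fasta_path), rebuild=True)

    def base(self, chrom: str, pos: int, info: dict | None = None) -> str:
        """Ancestral base (upper-case) or 'N' when unknown."""
        if self.info_tag is not None and info is not None:
            val = info.get(self.info_tag)
            if val:
                b = str(val)[0].upper()
                return b if b in VALID_BASES else "N"
            if self._fa is None:
                return "N"
        if self._fa is not None:
            try:
                b = str(self._fa[chrom][pos - 1: pos]).upper()
            except (KeyError, IndexError):
                return "N"
            return b if b in VALID_BASES else "N"
        return "N"


# ---------------------------------------------------------------------------
# VCF reading with the study's filter cascade
# ---------------------------------------------------------------------------

#: filter rule names, in the order they are applied; the first failing rule
#: gets the blame in filter_log
FILTER_ORDER = ("non_autosome", "non_snv", "multiallelic", "missing",
                "ancestral-unknown", "unpolarized", "cpg", "monomorphic")

_AUTOSOME_BAD = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}


def _is_cpg(ref_ctx: str, alleles: tuple[str, str]) -> bool:
    """CpG test on the reference context (left base, site, right base).

    A site is flagged CpG when either allele, placed at the site, forms a CG
    dinucleotide with an adjacent reference base.
    """
    left, _, right = ref_ctx[0], ref_ctx[1], ref_ctx[2]
    for allele in alleles:
        if allele == "G" and left == "C":
            return True
        if allele == "C" and right == "G":
            return True
    return False


def read_polarized_snps(variant_file: str | Path,
                        ancestral: AncestralSource,
                        reference: str | Path | None = None,
                        samples: Sequence[str] | None = None,
                        populations: dict[str, str] | None = None,
                        regions: dict[str, str] | None = None,
                        drop_cpg: bool = True,
                        autosomes_only: bool = True) -> SnpTable:
    """Read a VCF and apply the polarization filter cascade.

    Records pass, in order: autosomal, biallelic SNV, no missing genotype,
    polarizable (one of REF/ALT equals the ancestral base), not CpG, and
    polymorphic within the selected sample.  Each removal is charged to the
    first failing rule in ``SnpTable.filter_log``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(variant_file), gts012=True)
    all_samples = list(vcf.samples)
    if samples is None:
        samples = all_samples
        idx = np.arange(len(all_samples))
    else:
        missing_ids = [s for s in samples if s not in all_samples]
        if missing_ids:
            raise ValueError(f"unknown sample id(s): {', '.join(missing_ids)}")
        idx = np.array([all_samples.index(s) for s in samples])

    ref_fa = None
    if reference is not None:
        from pyfaidx import Fasta
        ref_fa = Fasta(str(reference), rebuild=True)

    populations = populations or {}
    regions = regions or {}
    individuals = [Individual(s, populations.get(s, "pop0"),
                              regions.get(s, "region0")) for s in samples]

    log = {k: 0 for k in FILTER_ORDER}
    records: list[SnpRecord] = []
    n_in = 0
    for var in vcf:
        n_in += 1
        chrom = var.CHROM
        if autosomes_only and chrom in _AUTOSOME_BAD:
            log["non_autosome"] += 1
            continue
        if not var.is_snp or var.ALT is None or len(var.ALT) == 0:
            log["non_snv"] += 1
            continue
        if len(var.ALT) > 1:
            log["multiallelic"] += 1
            continue
        ref_b, alt_b = var.REF.upper(), var.ALT[0].upper()
        if len(ref_b) != 1 or len(alt_b) != 1 or \
                ref_b not in VALID_BASES or alt_b not in VALID_BASES:
            log["non_snv"] += 1
            continue
        gt = np.asarray(var.gt_types)[idx]       # 0=hom-ref 1=het 2=hom-alt 3=missing
        if np.any(gt == 3):
            log["missing"] += 1
            continue
        info = dict(var.INFO)
        anc = ancestral.base(chrom, var.POS, info)
        if anc not in VALID_BASES:
            log["ancestral-unknown"] += 1
            continue
        if anc == ref_b:
            der, dos = alt_b, gt.astype(np.uint8)
        elif anc == alt_b:
            der, dos = ref_b, (2 - gt).astype(np.uint8)
        else:
            log["unpolarized"] += 1
            continue
        if drop_cpg and ref_fa is not None:
            try:
                ctx = str(ref_fa[chrom][var.POS - 2: var.POS + 1]).upper()
            except (KeyError, IndexError):
                ctx = "NNN"
            if len(ctx) == 3 and _is_cpg(ctx, (ref_b, alt_b)):
                log["cpg"] += 1
                continue
        total = int(dos.sum())
        if total == 0 or total == 2 * len(dos):
            log["monomorphic"] += 1
            continue
        records.append(SnpRecord(chrom, var.POS, anc, der, dos))

    log = {k: v for k, v in log.items() if v}
    retained = len(records)
    assert retained + sum(log.values()) == n_in
    return SnpTable(records, individuals, log)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_vcf(table: SnpTable, path: str | Path,
              aa_tag: str = "AA") -> None:
    """Write a SnpTable as a minimal VCF with the ancestral allele in INFO.

    REF is written as the ancestral base and ALT as the derived base, so
    genotypes encode derived dosage directly; re-reading through
    :func:`read_polarized_snps` round-trips records and dosages.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = list(dict.fromkeys(r.chrom for r in table.records))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f'##INFO=<ID={aa_tag},Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(i.sample_id for i in table.individuals) + "\n")
        for r in table.records:
            gts = "\t".join(gt_strings[int(d)] for d in r.dosages)
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ancestral}\t{r.derived}\t.\t"
                     f"PASS\t{aa_tag}={r.ancestral}\tGT\t{gts}\n")


def write_site_table(table, path: str | Path) -> None:
    """Write the annotated per-site TSV (missing values encoded NA)."""
    import pandas as pd
    df = site_dataframe(table)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def site_dataframe(table) -> "pd.DataFrame":
    import pandas as pd
    rows = []
    for i, r in enumerate(table.records):
        row = {"chrom": r.chrom, "pos": r.pos, "anc": r.ancestral,
               "der": r.derived, "derived_total": r.derived_total}
        ann = getattr(table, "annotations", None)
        if ann is not None:
            for key, arr in ann.items():
                row[key] = arr[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_filter_log(table: SnpTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"retained": len(table), "removed": table.filter_log}, fh,
                  indent=2)
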