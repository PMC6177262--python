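"""End-to-end orchestration: annotate → DAF̄ᵢ curves → SFS by class/bin →
pairwise SFS tests → bootstrap CIs → neutral-set export.

Every output table is a plain re-application of the module operations; the
pipeline adds only sequencing, bookkeeping and provenance (config hash,
seed) — nothing is computed here that cannot be re-derived by calling the
modules directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from . import dafi_stats, resampling, sfs_toolkit
from ._version import __version__
from .io_formats import (AncestralSource,
                         read_intervals, read_polarized_snps,
                         read_recombination_map, write_filter_log,
                         write_site_table)
from .snp_annotation import (AnnotatedSnpTable, NEUTRAL_RR_MIN, HOTSPOT_RR,
                             annotate_rates, assign_recombination_bins,
                             detect_hotspots, distance_to_nearest,
                             neutral_filter)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    map: str
    ancestral_fasta: str | None = None
    ancestral_tag: str | None = None
    reference_fasta: str | None = None
    transcribed_bed: str | None = None
    exons_bed: str | None = None
    conserved_bed: str | None = None
    populations: dict[str, str] = field(default_factory=dict)
    n_bins: int = 20
    rr_min: float = NEUTRAL_RR_MIN
    hotspot_rr: float = HOTSPOT_RR
    ntr_distance_bp: int = 50_000
    n_bootstrap: int = 0
    block_size: int = 100
    ci_level: float = 0.95
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "bgscan_out"

    def digest(self) -> str:
        # analysis-relevant fields only: the same analysis written to a
        # different directory carries the same provenance hash
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (f"# bgscan {__version__} config={config.digest()} "
            f"seed={config.seed}\n")


def _write(df, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def annotate(config: RunConfig) -> AnnotatedSnpTable:
    """Stage 1: read, filter, polarize and annotate the SNP table."""
    anc = AncestralSource(fasta_path=config.ancestral_fasta,
                          info_tag=config.ancestral_tag)
    table = read_polarized_snps(config.vcf, anc,
                                reference=config.reference_fasta,
                                populations=config.populations)
    logger.info("stage annotate: %d sites in, %d retained",
                len(table) + sum(table.filter_log.values()), len(table))
    atab = AnnotatedSnpTable.from_table(table)
    rmap = read_recombination_map(config.map)
    annotate_rates(atab, rmap)
    assign_recombination_bins(atab, config.n_bins)
    if config.transcribed_bed:
        tr = read_intervals(config.transcribed_bed, "transcribed")
        atab.annotations["in_tr"] = np.array(
            [tr.contains(r.chrom, r.pos) for r in atab.records])
    if config.exons_bed:
        ex = read_intervals(config.exons_bed, "exon")
        atab.annotations["dist_exon_bp"] = distance_to_nearest(
            atab, ex, units="bp")
        atab.annotations["dist_exon_cM"] = distance_to_nearest(
            atab, ex, rmap, units="cM")
    if config.conserved_bed:
        cons = read_intervals(config.conserved_bed, "conserved")
        atab.annotations["dist_conserved_cM"] = distance_to_nearest(
            atab, cons, rmap, units="cM")
    hot = detect_hotspots(rmap, config.hotspot_rr)
    if len(hot):
        atab.annotations["dist_hotspot_cM"] = distance_to_nearest(
            atab, hot, rmap, units="cM")
    atab._rmap = rmap
    return atab


def run_scan(config: RunConfig) -> dict:
    """Full analysis; returns the result bundle and writes its tables."""
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    stage = "annotate"
    try:
        atab = annotate(config)
        bundle["table"] = atab
        write_site_table(atab, out / "sites.tsv")
        write_filter_log(atab, out / "filter_log.json")

        stage = "dafi"
        curves = []
        class_masks = {"ALL": np.ones(len(atab), dtype=bool)}
        for cls in ("WS", "SW", "WWSS"):
            class_masks[cls] = atab.mutation_class == cls
        for cls, mask in class_masks.items():
            sub = atab.subset(mask)
            if len(sub) < config.n_bins:
                continue
            assign_recombination_bins(sub, config.n_bins)
            cdf = dafi_stats.dafi_curve(sub)
            cdf.insert(0, "class", cls)
            if config.n_bootstrap:
                cdf = _attach_bootstrap_ci(sub, cdf, config)
            curves.append(cdf)
        curves = pd.concat(curves, ignore_index=True)
        bundle["dafi_curves"] = curves
        _write(curves, out / "dafi_curves.tsv", config)

        stage = "sfs"
        n_dip = atab.n_individuals
        totals = atab.dosage_matrix().astype(np.int64).sum(axis=1)
        sfs_rows, site_sets = [], {}
        for cls, mask in class_masks.items():
            sub = atab.subset(mask)
            if len(sub) < config.n_bins:
                continue
            assign_recombination_bins(sub, config.n_bins)
            for b in (1, config.n_bins):     # lowest vs highest rate bin
                bmask = sub.bins == b
                if not bmask.any():
                    continue
                key = f"{cls}:bin{b}"
                site_sets[key] = sub.dosage_matrix().astype(
                    np.int64).sum(axis=1)[bmask]
                sfs = sfs_toolkit.unfolded_sfs(site_sets[key], n_dip)
                eta = sfs_toolkit.normalize_sfs(sfs)
                for i, (x, e) in enumerate(zip(sfs.xi, eta.xi), start=1):
                    sfs_rows.append({"set": key, "i": i, "xi": x, "eta": e})
        sfs_df = pd.DataFrame(sfs_rows)
        bundle["sfs"] = sfs_df
        _write(sfs_df, out / "sfs_by_class_bin.tsv", config)

        stage = "sfs-tests"
        tests = []
        pairs = list(combinations(sorted(site_sets), 2))
        for ka, kb in pairs:
            res = sfs_toolkit.sfs_permutation_test(
                site_sets[ka], site_sets[kb], n_dip,
                n_perm=config.n_perm, seed=config.seed)
            tests.append({"a": ka, "b": kb, "d_obs": res.d_obs, "p": res.p,
                          "p_bonferroni": min(1.0, res.p * len(pairs))})
        tests = pd.DataFrame(tests)
        bundle["sfs_tests"] = tests
        _write(tests, out / "sfs_tests.tsv", config)

        stage = "neutral-set"
        neutral = neutral_filter(atab, config.rr_min)
        bundle["neutral"] = neutral
        write_site_table(neutral, out / "neutral_sites.tsv")
        if len(neutral):
            export_neutral_sfs(bundle, out / "neutral_DAFpop0.obs")
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs "
                         "under %s", stage, out)
        raise
    return bundle


def _attach_bootstrap_ci(sub, cdf, config: RunConfig):
    """Block-bootstrap CIs for the per-bin group-mean DAF̄ᵢ curve."""
    chroms = [r.chrom for r in sub.records]
    blocks = resampling.make_blocks(len(sub), config.block_size,
                                    chrom_labels=chroms)
    bins = sub.bins
    regions = np.array([i.region for i in sub.individuals])
    groups = sorted(set(regions))
    bvals = sorted(cdf["bin"].unique())
    dos = sub.dosage_matrix().astype(np.int64)

    def stat(idx):
        # resampled sites keep their multiplicity (fancy indexing, not mask)
        vals = []
        for b in bvals:
            sel = idx[bins[idx] == b]
            if sel.size:
                d = dos[sel].sum(axis=0) / (2.0 * sel.size)
                vals.extend(float(d[regions == g].mean()) for g in groups)
            else:
                vals.extend([np.nan] * len(groups))
        return np.array(vals)

    dist = resampling.block_bootstrap(blocks, stat, config.n_bootstrap,
                                      seed=config.seed)
    dist = np.atleast_2d(dist)
    lows, highs = {}, {}
    for j, (b, g) in enumerate((b, g) for b in bvals for g in groups):
        lo, hi = resampling.ci(dist[:, j], config.ci_level)
        lows[(b, g)] = lo
        highs[(b, g)] = hi
    cdf["ci_low"] = [lows.get((b, g), np.nan)
                     for b, g in zip(cdf["bin"], cdf["group"])]
    cdf["ci_high"] = [highs.get((b, g), np.nan)
                      for b, g in zip(cdf["bin"], cdf["group"])]
    return cdf


def export_neutral_sfs(bundle: dict, path, population: str | None = None):
    """Write the neutral-set SFS as a fastsimcoal observed-SFS file.

    ``population`` restricts to one population's individuals (default: all).
    """
    neutral = bundle["neutral"]
    if population is None:
        cols = None
        n_dip = neutral.n_individuals
    else:
        cols = [j for j, ind in enumerate(neutral.individuals)
                if ind.population == population]
        if not cols:
            raise ValueError(f"population {population!r} not in bundle")
        n_dip = len(cols)
    sfs = sfs_toolkit.sfs_from_table(neutral, individuals=cols)
    sfs_toolkit.write_fastsimcoal_sfs(sfs, path)
    return sfs
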