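"""Block bootstrap over runs of adjacent SNPs.

Statistics computed over SNPs (DAF̄ᵢ, SFS entries) are locally
autocorrelated through linkage, so confidence intervals resample blocks of
100 adjacent SNPs (within the analysed subset, per chromosome by default)
with replacement, keeping the resampled site count equal to the original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

DEFAULT_BLOCK_SIZE = 100


@dataclass
class BlockSet:
    """Non-overlapping runs of site indices whose concatenation restores the
    original site order."""

    blocks: list[np.ndarray]
    block_size: int
    n_sites: int

    def __len__(self) -> int:
        return len(self.blocks)


def make_blocks(site_order: Sequence[int] | int,
                block_size: int = DEFAULT_BLOCK_SIZE,
                chrom_labels: Sequence | None = None) -> BlockSet:
    """Cut an ordered site list into runs of ``block_size`` adjacent SNPs.

    ``site_order`` is either the site count (indices 0..n-1 assumed in
    genomic order) or an explicit index sequence.  Adjacency is within the
    analysed subset, not physical bp adjacency.  With ``chrom_labels``,
    blocks never span a chromosome boundary.  The last block per chromosome
    may be shorter.
    """
    if isinstance(site_order, (int, np.integer)):
        idx = np.arange(site_order)
    else:
        idx = np.asarray(site_order)
    if idx.size == 0:
        raise ValueError("empty site list")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if idx.size < block_size:
        warnings.warn(f"only {idx.size} sites for block size {block_size}: "
                      "a single short block")
    blocks: list[np.ndarray] = []
    if chrom_labels is None:
        runs = [idx]
    else:
        labels = np.asarray(chrom_labels)
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        runs = np.split(idx, change)
    for run in runs:
        for start in range(0, len(run), block_size):
            blocks.append(run[start: start + block_size])
    return BlockSet(blocks, block_size, int(idx.size))


def block_bootstrap(blocks: BlockSet,
                    statistic: Callable[[np.ndarray], float | np.ndarray],
                    n_rep: int = 1000,
                    seed: int | None = None) -> np.ndarray:
    """Bootstrap distribution of ``statistic`` over block resamples.

    Each replicate draws blocks uniformly with replacement until the
    resampled site count equals the original; the final draw is truncated if
    it overshoots.  ``statistic`` receives an index array into the original
    site sequence.  Failing replicates are recorded as NaN and reported.

    Returns an array of shape (n_rep,) or (n_rep, k) for vector statistics —
    all components of a vector statistic share the block draws within a
    replicate.
    """
    rng = np.random.default_rng(seed)
    sizes = np.array([len(b) for b in blocks.blocks])
    target = blocks.n_sites
    out = None
    n_failed = 0
    # upper bound on draws per replicate: all-minimum-size blocks
    max_draws = int(np.ceil(target / sizes.min())) + 1
    for rep in range(n_rep):
        draws = rng.integers(0, len(blocks.blocks), size=max_draws)
        csum = np.cumsum(sizes[draws])
        stop = int(np.searchsorted(csum, target))
        chosen = draws[: stop + 1]
        idx = np.concatenate([blocks.blocks[j] for j in chosen])[:target]
        try:
            val = statistic(idx)
        except Exception:
            n_failed += 1
            val = np.nan
        val = np.atleast_1d(np.asarray(val, dtype=float))
        if out is None:
            out = np.full((n_rep, val.size), np.nan)
        out[rep, : val.size] = val
    if n_failed:
        warnings.warn(f"{n_failed}/{n_rep} bootstrap replicates failed "
                      "(recorded as NaN)")
    return out[:, 0] if out.shape[1] == 1 else out


def ci(distribution: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical central confidence interval from a bootstrap distribution.

    Quantiles (1-level)/2 and 1-(1-level)/2 of the non-missing values,
    type-7 linear interpolation (numpy default).
    """
    d = np.asarray(distribution, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 10:
        raise ValueError(f"only {d.size} non-missing replicates; need >= 10")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
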