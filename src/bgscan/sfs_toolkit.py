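"""Unfolded site-frequency-spectrum tools.

Covers construction from dosage data, normalization against the stationary
expectation (xi_i ∝ 1/i, so a flat normalized SFS means a constant-size
neutral population), hypergeometric projection to a smaller sample size,
a squared-difference distance between spectra, and a permutation test for
whether two sets of sites carry the same spectrum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom


@dataclass
class SFSVector:
    """Unfolded SFS for m haploid genomes: entries for derived counts 1..m-1.

    Entries are real-valued (projection produces fractional masses).
    """

    m: int
    xi: np.ndarray
    n_skipped: int = 0        # monomorphic sites dropped during construction

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        if len(self.xi) != self.m - 1:
            raise ValueError(f"SFS for m={self.m} needs {self.m - 1} entries, "
                             f"got {len(self.xi)}")
        if np.any(self.xi < 0):
            raise ValueError("negative SFS entry")

    @property
    def s(self) -> float:
        return float(self.xi.sum())

    def proportions(self) -> np.ndarray:
        if self.s == 0:
            raise ValueError("empty SFS has no proportion form")
        return self.xi / self.s

    def __eq__(self, other) -> bool:
        return (isinstance(other, SFSVector) and self.m == other.m
                and np.array_equal(self.xi, other.xi))


def unfolded_sfs(derived_totals, n_diploids: int) -> SFSVector:
    """SFS from per-site derived-allele totals in a sample of n diploids.

    Sites with total 0 or 2n (monomorphic) are skipped and counted in
    ``n_skipped``.
    """
    totals = np.asarray(derived_totals, dtype=np.int64)
    if totals.size == 0:
        raise ValueError("no sites")
    m = 2 * n_diploids
    if totals.min() < 0 or totals.max() > m:
        raise ValueError("derived total outside 0..2n")
    poly = totals[(totals > 0) & (totals < m)]
    counts = np.bincount(poly, minlength=m)[1:m]
    return SFSVector(m, counts.astype(float),
                     n_skipped=int(totals.size - poly.size))


def sfs_from_table(table, site_mask=None, individuals=None) -> SFSVector:
    """SFS of a SnpTable (optionally a site subset / individual subset)."""
    sub = table if site_mask is None else table.subset(site_mask)
    dos = sub.dosage_matrix().astype(np.int64)
    if individuals is not None:
        dos = dos[:, individuals]
    return unfolded_sfs(dos.sum(axis=1), dos.shape[1])


def stationary_expectation(m: int) -> np.ndarray:
    """Relative stationary expectation 1/i for i = 1..m-1 (unit total mass)."""
    i = np.arange(1, m)
    e = 1.0 / i
    return e / e.sum()


def normalize_sfs(sfs: SFSVector) -> SFSVector:
    """Divide each entry by its constant-size stationary expectation.

    eta_i = xi_i * i * a / s  with  a = sum_{j<m} 1/j; a stationary spectrum
    (xi_i ∝ 1/i) maps to all-ones.
    """
    if sfs.s == 0:
        raise ValueError("cannot normalize an empty SFS")
    i = np.arange(1, sfs.m)
    a = float(np.sum(1.0 / i))
    return SFSVector(sfs.m, sfs.xi * i * a / sfs.s, n_skipped=sfs.n_skipped)


def project_sfs(sites, m_target: int) -> SFSVector:
    """Project an SFS down to ``m_target`` haploid genomes.

    ``sites`` is either an SFSVector (uniform full sample size m) or a
    sequence of ``(n_j, f_j)`` pairs (full sample size and derived count per
    site).  Each site contributes to class i the probability that a
    hypergeometric subsample of size m_target contains exactly i derived
    copies:

        P(i | n, f) = C(f, i) C(n-f, m_target-i) / C(n, m_target)

    Classes i = 0 and i = m_target (monomorphic after subsampling) are
    discarded, so projected spectra sum to less than the input site count.
    """
    if isinstance(sites, SFSVector):
        n = np.full(sites.m - 1, sites.m, dtype=np.int64)
        f = np.arange(1, sites.m, dtype=np.int64)
        w = sites.xi
    else:
        arr = np.asarray(list(sites), dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("sites must be (n_j, f_j) pairs")
        n, f = arr[:, 0], arr[:, 1]
        if np.any((f < 1) | (f > n - 1)):
            raise ValueError("derived count must be in 1..n_j-1")
        w = np.ones(len(arr))
    if m_target < 2:
        raise ValueError("m_target must be >= 2")
    if np.any(m_target > n):
        raise ValueError("m_target exceeds a site's sample size")

    xi = np.zeros(m_target - 1)
    # group identical (n, f) pairs: one pmf evaluation per distinct pair
    uniq, inv = np.unique(np.stack([n, f], axis=1), axis=0,
                          return_inverse=True)
    weights = np.zeros(len(uniq))
    np.add.at(weights, inv, w)
    i = np.arange(1, m_target)
    for (nj, fj), wj in zip(uniq, weights):
        if wj == 0:
            continue
        xi += wj * hypergeom.pmf(i, nj, fj, m_target)
    return SFSVector(m_target, xi)


def sfs_distance(a: SFSVector, b: SFSVector, form: str = "proportion") -> float:
    """Sum of squared entry-wise differences between two spectra.

    ``form='proportion'`` (default) compares each spectrum divided by its own
    total so sets of unequal size are comparable; ``form='normalized'``
    compares stationarity-normalized entries.
    """
    if a.m != b.m:
        raise ValueError(f"sample sizes differ: {a.m} vs {b.m}")
    if form == "proportion":
        pa, pb = a.proportions(), b.proportions()
    elif form == "normalized":
        pa, pb = normalize_sfs(a).xi, normalize_sfs(b).xi
    else:
        raise ValueError("form must be 'proportion' or 'normalized'")
    return float(np.sum((pa - pb) ** 2))


@dataclass
class SfsTestResult:
    """Permutation-test outcome for equality of two spectra.

    In Monte-Carlo mode p = (1 + #{D_perm >= D_obs}) / (1 + n_perm); in
    exact (full-enumeration) mode p = #{D >= D_obs} / #splits.
    """

    d_obs: float
    d_perm: np.ndarray
    n_perm: int
    mode: str
    exact: bool = False
    p: float = field(init=False)

    def __post_init__(self):
        ge = int(np.count_nonzero(self.d_perm >= self.d_obs - 1e-15))
        if self.exact:
            self.p = ge / len(self.d_perm)
        else:
            self.p = (1 + ge) / (1 + self.n_perm)


def _split_shared(sites_a, sites_b, ids_a, ids_b):
    """Partition into (shared totals, private-a totals, private-b totals)."""
    a = np.asarray(sites_a, dtype=np.int64)
    b = np.asarray(sites_b, dtype=np.int64)
    if ids_a is None or ids_b is None:
        return np.empty(0, dtype=np.int64), a, b
    ids_a = np.asarray(ids_a)
    ids_b = np.asarray(ids_b)
    common = np.intersect1d(ids_a, ids_b)
    in_a = np.isin(ids_a, common)
    in_b = np.isin(ids_b, common)
    return a[in_a], a[~in_a], b[~in_b]


def sfs_permutation_test(sites_a, sites_b, n_diploids: int,
                         n_perm: int = 1000, seed: int | None = None,
                         mode: str = "disjoint", ids_a=None, ids_b=None,
                         exact: bool = False,
                         exact_cap: int = 500_000) -> SfsTestResult:
    """Permutation test for a difference between the spectra of two site sets.

    Sites enter as per-site derived totals (same haploid sample size
    m = 2 n_diploids on both sides).  Two null schemes:

    - ``mode='disjoint'`` (also covers overlapping sets when ids are given):
      sites shared by both sets stay fixed; the private sites are pooled and
      randomly re-split preserving the two private counts, the distance
      recomputed per replicate.
    - ``mode='nested'`` (a ⊆ b): each replicate draws |a| sites from b
      without replacement and computes its distance to the full set's SFS.

    With ``exact=True`` and a feasible number of splits, all re-splits (or
    subsets) are enumerated instead of sampled.
    """
    a = np.asarray(sites_a, dtype=np.int64)
    b = np.asarray(sites_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both site sets must be non-empty")
    m = 2 * n_diploids
    rng = np.random.default_rng(seed)

    sfs_a = unfolded_sfs(a, n_diploids)
    sfs_b = unfolded_sfs(b, n_diploids)
    d_obs = sfs_distance(sfs_a, sfs_b)

    def counts(totals):
        poly = totals[(totals > 0) & (totals < m)]
        return np.bincount(poly, minlength=m)[1:m].astype(float)

    if mode == "nested":
        # subset check on ids when available, else on the multiset of totals
        if ids_a is not None and ids_b is not None:
            if not np.all(np.isin(np.asarray(ids_a), np.asarray(ids_b))):
                raise ValueError("nested mode requires a ⊆ b")
        else:
            ca = np.bincount(a, minlength=m + 1)
            cb = np.bincount(b, minlength=m + 1)
            if np.any(ca > cb):
                raise ValueError("nested mode requires a ⊆ b")
        k = len(a)
        n_splits = math.comb(len(b), k)
        if exact and n_splits <= exact_cap:
            d = np.array([
                sfs_distance(unfolded_sfs(b[list(c)], n_diploids), sfs_b)
                for c in itertools.combinations(range(len(b)), k)])
            return SfsTestResult(d_obs, d, len(d), mode, exact=True)
        d = np.empty(n_perm)
        for t in range(n_perm):
            sub = rng.choice(b, size=k, replace=False)
            d[t] = sfs_distance(unfolded_sfs(sub, n_diploids), sfs_b)
        return SfsTestResult(d_obs, d, n_perm, mode)

    if mode != "disjoint":
        raise ValueError("mode must be 'disjoint' or 'nested'")

    shared, priv_a, priv_b = _split_shared(a, b, ids_a, ids_b)
    shared_counts = counts(shared)
    pool = np.concatenate([priv_a, priv_b])
    ka = len(priv_a)

    def dist_from_split(sel_a_counts, sel_b_counts):
        ca = shared_counts + sel_a_counts
        cb = shared_counts + sel_b_counts
        sa, sb = ca.sum(), cb.sum()
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.sum((ca / sa - cb / sb) ** 2))

    n_splits = math.comb(len(pool), ka)
    if exact and n_splits <= exact_cap:
        idx_all = set(range(len(pool)))
        d = []
        for comb in itertools.combinations(range(len(pool)), ka):
            sel = np.fromiter(comb, dtype=np.int64, count=ka)
            rest = np.fromiter(idx_all - set(comb), dtype=np.int64)
            d.append(dist_from_split(counts(pool[sel]), counts(pool[rest])))
        return SfsTestResult(d_obs, np.asarray(d), len(d), mode, exact=True)

    # Monte-Carlo: permute the pooled totals, split at ka.  The tiled
    # matrix form is fastest but only used while it stays small.
    d = np.empty(n_perm)
    if n_perm * pool.size <= 20_000_000:
        perm = rng.permuted(np.tile(pool, (n_perm, 1)), axis=1)
        for t in range(n_perm):
            d[t] = dist_from_split(counts(perm[t, :ka]),
                                   counts(perm[t, ka:]))
    else:
        work = pool.copy()
        for t in range(n_perm):
            rng.shuffle(work)
            d[t] = dist_from_split(counts(work[:ka]), counts(work[ka:]))
    return SfsTestResult(d_obs, d, n_perm, mode)


# ---------------------------------------------------------------------------
# fastsimcoal-compatible observed-SFS export
# ---------------------------------------------------------------------------

def write_fastsimcoal_sfs(sfs: SFSVector, path: str | Path,
                          n_monomorphic: float = 0.0) -> None:
    """One-population derived-allele observed SFS (_DAFpop0.obs dialect).

    m+1 entries for derived counts 0..m; class 0 holds ``n_monomorphic``
    (0 unless provided), class m is 0 for spectra built from polymorphic
    sites.
    """
    entries = np.concatenate([[n_monomorphic], sfs.xi, [0.0]])
    header = "\t".join(f"d0_{i}" for i in range(sfs.m + 1))
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write(header + "\n")
        fh.write("\t".join(repr(float(x)) for x in entries) + "\n")


def read_fastsimcoal_sfs(path: str | Path) -> SFSVector:
    """Re-import a one-population derived-allele observed SFS file."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    entries = np.array([float(x) for x in lines[2].split()])
    m = len(entries) - 1
    return SFSVector(m, entries[1:m])
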