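"""Linkage disequilibrium: pairwise r^2, decay curves, pruning, thresholds.

r^2 is the squared Pearson correlation of unphased genotype dosage vectors
(0/1/2) — the Rogers-Huff composite estimator — computed pairwise-complete
over samples genotyped at both sites.  Pairs are always intra-chromosomal and
distances are measured between 1-based positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variantio import VariantTable


@dataclass
class LdBin:
    lo: int                # bp, inclusive
    hi: int                # bp, exclusive
    mean_r2: float         # NaN for an empty bin
    n_pairs: int

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass
class PruneResult:
    retained: list[int]
    removed: list[int]
    window_snps: int
    step_snps: int
    r2_max: float


def r2_pair(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Squared dosage correlation of two sites; NaN when fewer than two
    jointly genotyped samples remain or either site has zero variance."""
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return float("nan")
    va = a - a.mean()
    vb = b - b.mean()
    denom = np.sqrt((va**2).sum() * (vb**2).sum())
    if denom == 0:
        return float("nan")
    r = float((va * vb).sum() / denom)
    return r * r


def r2_matrix(g: np.ndarray) -> np.ndarray:
    """All-pairs pairwise-complete r^2 for a (n_sites, n_samples) dosage
    block (missing = -1); algebraically identical to calling
    :func:`r2_pair` on every pair, but in matrix form.
    """
    ok = (g >= 0).astype(float)
    a = np.where(g >= 0, g, 0).astype(float)
    n = ok @ ok.T                      # jointly genotyped samples per pair
    sx = a @ ok.T                      # sum of x over the joint support
    sxx = (a * a) @ ok.T
    sxy = a @ a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        vary = varx.T
        r2 = cov**2 / (varx * vary)
        r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_decay_curve(table: VariantTable, samples: Sequence[str] | None,
                   max_dist_bp: int, bin_bp: int) -> list[LdBin]:
    """Mean r^2 by distance bin over all intra-chromosomal pairs within
    max_dist_bp.  Bins are contiguous [0, bin), [bin, 2*bin), ... up to
    max_dist_bp.  Callers should apply the MAF filter first."""
    idx = table.sample_indices(samples)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in pd.unique(table.chrom):
        m = table.chrom == chrom
        pos = table.pos[m]
        g = table.gt[np.ix_(m.nonzero()[0], idx)]
        r2 = r2_matrix(g)
        iu, ju = np.triu_indices(len(pos), k=1)
        dist = pos[ju] - pos[iu]
        vals = r2[iu, ju]
        use = (dist <= max_dist_bp) & np.isfinite(vals)
        bins = np.minimum(dist[use] // bin_bp, n_bins - 1).astype(int)
        np.add.at(sums, bins, vals[use])
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return [LdBin(b * bin_bp, min((b + 1) * bin_bp, max_dist_bp),
                  float(means[b]), int(counts[b])) for b in range(n_bins)]


def half_decay_distance(curve: list[LdBin]) -> tuple[float, bool]:
    """Smallest bin midpoint where mean r^2 <= max(mean r^2) / 2.

    Returns (distance_bp, reached).  reached is False (and the distance NaN)
    when the curve never falls to half its maximum within the evaluated
    range, or when every bin is empty.
    """
    vals = np.array([b.mean_r2 for b in curve])
    fin = np.isfinite(vals)
    if not fin.any():
        return float("nan"), False
    half = np.nanmax(vals) / 2.0
    for b, v in zip(curve, vals):
        if np.isfinite(v) and v <= half:
            return float(b.midpoint), True
    return float("nan"), False


def curve_frame(curve: list[LdBin]) -> pd.DataFrame:
    return pd.DataFrame([{"bin_lo": b.lo, "bin_hi": b.hi,
                          "mean_r2": b.mean_r2, "n_pairs": b.n_pairs}
                         for b in curve])


def ld_prune(table: VariantTable, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.5, samples: Sequence[str] | None = None,
             ) -> PruneResult:
    """Greedy sliding-window LD pruning (window/step in SNP counts).

    Within each window, while any surviving pair has r^2 >= r2_max the pair
    with the smallest indices is resolved by removing the member with the
    lower MAF (equal MAF: the downstream site).  After the scan no surviving
    pair within any window has r^2 >= r2_max, so re-pruning the retained set
    is a fixed point.
    """
    idx = table.sample_indices(samples)
    maf = table.maf(idx)
    removed: set[int] = set()
    cache: dict[tuple[int, int], float] = {}

    def r2_of(i: int, j: int) -> float:
        key = (i, j)
        if key not in cache:
            cache[key] = r2_pair(table.gt[i, idx], table.gt[j, idx])
        return cache[key]

    for chrom in pd.unique(table.chrom):
        active = list(np.flatnonzero(table.chrom == chrom))
        # windows slide over the *surviving* SNP list; passes repeat until no
        # removal, which makes pruning a fixed point on the retained set
        while True:
            dropped_in_pass = False
            start = 0
            while start < len(active):
                window = active[start:start + window_snps]
                changed = True
                while changed:
                    changed = False
                    for ai in range(len(window)):
                        if changed:
                            break
                        for bi in range(ai + 1, len(window)):
                            i, j = window[ai], window[bi]
                            r2 = r2_of(i, j)
                            if np.isfinite(r2) and r2 >= r2_max:
                                if maf[i] < maf[j]:
                                    drop = i
                                elif maf[j] < maf[i]:
                                    drop = j
                                else:
                                    drop = j   # equal MAF: downstream site
                                removed.add(drop)
                                window.remove(drop)
                                active.remove(drop)
                                changed = True
                                dropped_in_pass = True
                                break
                start += step_snps
            if not dropped_in_pass:
                break
    retained = [i for i in range(table.n_sites) if i not in removed]
    return PruneResult(retained=retained, removed=sorted(removed),
                       window_snps=window_snps, step_snps=step_snps,
                       r2_max=r2_max)


def significance_threshold(independent_snp_count: int) -> float:
    """Per-test p-value threshold: 1 / (effective number of independent
    SNPs), e.g. 1/863,148 = 1.16e-6."""
    if independent_snp_count <= 0:
        raise ValueError("independent_snp_count must be > 0")
    return 1.0 / independent_snp_count
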