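"""Windowed diversity and differentiation statistics.

Per-bp pairwise diversity (theta_pi), Watterson's theta, Tajima's D,
the Weir & Cockerham (1984) FST estimator, sliding-window scans, and the
per-individual inbreeding coefficient F = (O_hom - E_hom) / (N - E_hom).

All estimators work directly on the alt-dosage genotype matrix with
pairwise-complete treatment of missing calls: a missing genotype simply
removes that sample's two allele copies from the site's counts.  Window
denominators use the total window length in bp.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RegionError
from .variantio import HET, HOM_ALT, HOM_REF, MISSING, PopulationMap, VariantTable


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class DiversityWindow:
    chrom: str
    start: int                 # 0-based half-open
    end: int
    population: str
    S: int                     # segregating sites
    n_eff: float               # mean non-missing allele copies at counted sites
    theta_pi: float            # per bp
    theta_w: float             # per bp
    tajima_d: float            # NaN when undefined
    d_flag: str = ""           # "", "no_segregating", "few_segregating", "m_varies"
    partial: bool = False      # last short window of a chromosome


@dataclass
class FstWindow:
    chrom: str
    start: int
    end: int
    pop_a: str
    pop_b: str
    fst: float                 # NaN when undefined in the window
    n_sites: int
    partial: bool = False


@dataclass
class InbreedingRecord:
    sample: str
    o_hom: int
    e_hom: float
    n_sites: int
    f: float


# ---------------------------------------------------------------------------
# per-site counts
# ---------------------------------------------------------------------------

def _site_counts(table: VariantTable, sample_idx: np.ndarray,
                 site_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele copies k and total non-missing copies m per selected site."""
    g = table.gt[np.ix_(site_mask.nonzero()[0], sample_idx)]
    ok = g >= 0
    m = 2 * ok.sum(axis=1)
    k = np.where(ok, g, 0).sum(axis=1)
    return k.astype(np.int64), m.astype(np.int64)


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (0 for n < 2)."""
    if n < 2:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n)))


def _check_region(start: int, end: int) -> int:
    length = end - start
    if length <= 0:
        raise RegionError(f"empty region [{start}, {end})")
    return length


def theta_pi(table: VariantTable, samples: Sequence[str] | None,
             region: tuple[str, int, int]) -> float:
    """Per-bp pairwise diversity over a 0-based half-open region:
    sum over sites of 2*k*(m-k)/(m*(m-1)), divided by region length."""
    chrom, start, end = region
    length = _check_region(start, end)
    idx = table.sample_indices(samples)
    k, m = _site_counts(table, idx, table.sites_in(chrom, start, end))
    use = m >= 2
    k, m = k[use], m[use]
    if len(k) == 0:
        return 0.0
    terms = 2.0 * k * (m - k) / (m * (m - 1.0))
    return float(terms.sum() / length)


def theta_w(table: VariantTable, samples: Sequence[str] | None,
            region: tuple[str, int, int]) -> float:
    """Per-bp Watterson estimator; with per-site sample sizes m_i the
    contribution of each segregating site is 1/a_{m_i}."""
    chrom, start, end = region
    length = _check_region(start, end)
    idx = table.sample_indices(samples)
    k, m = _site_counts(table, idx, table.sites_in(chrom, start, end))
    seg = (k > 0) & (k < m) & (m >= 2)
    if not seg.any():
        return 0.0
    inv_a = np.array([1.0 / harmonic(int(mi)) for mi in m[seg]])
    return float(inv_a.sum() / length)


def _tajima_constants(m: int) -> tuple[float, float]:
    """e1, e2 of Tajima (1989) for sample size m (allele copies)."""
    a1 = harmonic(m)
    a2 = float(np.sum(1.0 / np.arange(1, m) ** 2))
    b1 = (m + 1.0) / (3.0 * (m - 1.0))
    b2 = 2.0 * (m * m + m + 3.0) / (9.0 * m * (m - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2.0) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajima_d(table: VariantTable, samples: Sequence[str] | None,
             region: tuple[str, int, int]) -> tuple[float, str]:
    """Tajima's D for the region, plus a quality flag.

    Returns (nan, "no_segregating") when S = 0.  The sample size entering the
    variance constants is the modal per-site m; windows where m varies by more
    than 10% around the mode are flagged "m_varies", and S < 3 is flagged
    "few_segregating" (the value is still returned).
    """
    chrom, start, end = region
    _check_region(start, end)
    idx = table.sample_indices(samples)
    k, m = _site_counts(table, idx, table.sites_in(chrom, start, end))
    use = m >= 2
    k, m = k[use], m[use]
    seg = (k > 0) & (k < m)
    S = int(seg.sum())
    if S == 0:
        return float("nan"), "no_segregating"
    flag = ""
    vals, counts = np.unique(m[seg], return_counts=True)
    m_mode = int(vals[np.argmax(counts)])
    if np.any(np.abs(m[seg] - m_mode) > 0.1 * m_mode):
        flag = "m_varies"
    elif S < 3:
        flag = "few_segregating"
    pi_sum = float((2.0 * k[seg] * (m[seg] - k[seg])
                    / (m[seg] * (m[seg] - 1.0))).sum())
    a1 = harmonic(m_mode)
    e1, e2 = _tajima_constants(m_mode)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan"), flag or "few_segregating"
    return float((pi_sum - S / a1) / np.sqrt(var)), flag


def fst_wc(table: VariantTable, pop_a: Sequence[str], pop_b: Sequence[str],
           region: tuple[str, int, int], names: tuple[str, str] = ("A", "B"),
           ) -> FstWindow:
    """Weir & Cockerham (1984) weighted FST: sum(a) / sum(a + b + c) over
    sites, two populations, from genotype counts (no phasing needed)."""
    chrom, start, end = region
    _check_region(start, end)
    ia = table.sample_indices(pop_a)
    ib = table.sample_indices(pop_b)
    mask = table.sites_in(chrom, start, end)
    rows = mask.nonzero()[0]
    ga = table.gt[np.ix_(rows, ia)]
    gb = table.gt[np.ix_(rows, ib)]

    def counts(g):
        ok = g >= 0
        n = ok.sum(axis=1).astype(float)           # genotyped individuals
        p = np.where(ok, g, 0).sum(axis=1) / np.maximum(2 * n, 1)
        h = (g == HET).sum(axis=1) / np.maximum(n, 1)
        return n, p, h

    na, pa, ha = counts(ga)
    nb, pb, hb = counts(gb)
    use = (na >= 1) & (nb >= 1) & ((na * 2 >= 2) & (nb * 2 >= 2))
    # polymorphic across the two populations (monomorphic sites contribute 0)
    na, pa, ha, nb, pb, hb = (x[use] for x in (na, pa, ha, nb, pb, hb))
    r = 2.0
    nbar = (na + nb) / r
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1.0)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (na * ha + nb * hb) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    fin = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = a[fin], b[fin], c[fin]
    denom = float((a + b + c).sum())
    fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstWindow(chrom, start, end, names[0], names[1], fst, int(fin.sum()))


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def window_grid(length: int, window_bp: int, step_bp: int,
                ) -> list[tuple[int, int, bool]]:
    """(start, end, partial) windows tiling [0, length) from position 0.

    Full windows start at 0, step, 2*step, ... while start + window <= length;
    trailing partial windows are retained and flagged."""
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    out = []
    start = 0
    while start < length:
        end = start + window_bp
        if end <= length:
            out.append((start, end, False))
        else:
            out.append((start, length, True))
        start += step_bp
    return out


def windowed_scan(table: VariantTable, pops: dict[str, Sequence[str]],
                  window_bp: int, step_bp: int,
                  statistics: Iterable[str] = ("diversity", "fst"),
                  ) -> tuple[list[DiversityWindow], list[FstWindow]]:
    """Sliding-window scan over every chromosome of the table.

    ``pops`` maps population name -> member sample ids.  "diversity" produces
    one DiversityWindow per population per window; "fst" one FstWindow per
    unordered population pair per window.
    """
    statistics = set(statistics)
    div_out: list[DiversityWindow] = []
    fst_out: list[FstWindow] = []
    pop_names = list(pops)
    chroms = list(table.contigs) or list(pd.unique(table.chrom))
    for chrom in chroms:
        length = table.contigs.get(chrom)
        if length is None:
            m = table.chrom == chrom
            length = int(table.pos[m].max()) if m.any() else 0
        for start, end, partial in window_grid(length, window_bp, step_bp):
            region = (chrom, start, end)
            if "diversity" in statistics:
                for name in pop_names:
                    idx = table.sample_indices(pops[name])
                    k, m = _site_counts(table, idx,
                                        table.sites_in(chrom, start, end))
                    use = m >= 2
                    k_, m_ = k[use], m[use]
                    seg = (k_ > 0) & (k_ < m_)
                    d, flag = tajima_d(table, pops[name], region)
                    div_out.append(DiversityWindow(
                        chrom, start, end, name,
                        S=int(seg.sum()),
                        n_eff=float(m_.mean()) if len(m_) else 0.0,
                        theta_pi=theta_pi(table, pops[name], region),
                        theta_w=theta_w(table, pops[name], region),
                        tajima_d=d, d_flag=flag, partial=partial))
            if "fst" in statistics:
                for i in range(len(pop_names)):
                    for j in range(i + 1, len(pop_names)):
                        w = fst_wc(table, pops[pop_names[i]], pops[pop_names[j]],
                                   region, names=(pop_names[i], pop_names[j]))
                        w.partial = partial
                        fst_out.append(w)
    return div_out, fst_out


def diversity_frame(windows: list[DiversityWindow]) -> pd.DataFrame:
    return pd.DataFrame([vars(w) for w in windows])


def fst_frame(windows: list[FstWindow]) -> pd.DataFrame:
    return pd.DataFrame([vars(w) for w in windows])


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def inbreeding_coefficient(table: VariantTable, sample: str,
                           ) -> InbreedingRecord:
    """Per-individual F from observed vs expected homozygosity.

    E_hom at a site with cohort alt frequency p and m non-missing allele
    copies is 1 - 2p(1-p) * m/(m-1) (the small-sample-corrected expected
    heterozygosity under Hardy-Weinberg); sites genotyped in the sample and
    polymorphic in the cohort are counted.
    """
    j = table.sample_index(sample)
    g = table.gt[:, j]
    ok_all = table.gt >= 0
    m = 2 * ok_all.sum(axis=1)
    k = np.where(ok_all, table.gt, 0).sum(axis=1)
    use = (g >= 0) & (m >= 2) & (k > 0) & (k < m)
    p = k[use] / m[use]
    e_het = 2.0 * p * (1 - p) * m[use] / (m[use] - 1.0)
    e_hom = float((1.0 - e_het).sum())
    o_hom = int(((g[use] == HOM_REF) | (g[use] == HOM_ALT)).sum())
    n = int(use.sum())
    denom = n - e_hom
    f = float("nan") if denom == 0 else (o_hom - e_hom) / denom
    return InbreedingRecord(sample, o_hom, e_hom, n, float(f))
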