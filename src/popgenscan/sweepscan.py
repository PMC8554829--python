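"""Composite selective-sweep scan.

Three signals are combined over windows: the Z-standardized ratio of
background to focal nucleotide diversity, the Z-standardized
Weir-Cockerham FST, and a mu statistic that multiplies a diversity factor, an
SFS-tail factor and an LD-contrast factor over SNP windows:

    mu      = mu_var * mu_sfs * mu_ld
    mu_var  = span_bp * S_total / (W * L)
    mu_sfs  = (xi_1 + xi_{m-1}) / W
    mu_ld   = (mean r^2 left half + mean r^2 right half)
              / (2 * mean r^2 across halves + eps)

for a window of W consecutive SNPs spanning span_bp on a chromosome of
length L carrying S_total SNPs, with xi_1 the singleton count and xi_{m-1}
the count of sites one copy short of fixation (derived counts when a
polarized matrix is supplied, minor-allele counts otherwise).  mu_var has
neutral expectation ~1 and rises over the SNP-sparse valley of a sweep;
mu_sfs rises with the low/high-frequency SFS distortion that hitchhiking
leaves; mu_ld rises when LD is high within each flank but broken across the
sweep center.

Windows qualifying on the configured combination (default: all three — Z > 3
for both Z statistics and top 5% for mu) are merged into maximal candidate
regions, and genes overlapping a region by >= 1 bp are reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError, WindowError
from .lddecay import r2_matrix
from .popstats import DiversityWindow, FstWindow
from .variantio import VariantTable

MU_EPS = 1e-6


@dataclass
class MuWindow:
    chrom: str
    start_pos: int            # 1-based position of first SNP in window
    end_pos: int              # 1-based position of last SNP
    mu: float
    mu_var: float
    mu_sfs: float
    mu_ld: float

    @property
    def midpoint(self) -> float:
        return (self.start_pos + self.end_pos) / 2.0


@dataclass
class SweepWindow:
    chrom: str
    start: int                # 0-based half-open
    end: int
    pi_focal: float
    pi_background: float
    pi_ratio: float           # background / focal; NaN when focal pi == 0
    z_pi: float
    fst: float
    z_fst: float
    mu_hit: bool              # contains a top-fraction mu window midpoint
    flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    criteria: tuple[str, ...]
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Z statistics
# ---------------------------------------------------------------------------

def _zscores(values: np.ndarray) -> np.ndarray:
    """Z over finite entries (population sd); non-finite stay NaN."""
    fin = np.isfinite(values)
    out = np.full(len(values), np.nan)
    if fin.sum() >= 2:
        mean = values[fin].mean()
        sd = values[fin].std()
        if sd > 0:
            out[fin] = (values[fin] - mean) / sd
        else:
            out[fin] = 0.0
    elif fin.sum() == 1:
        out[fin] = 0.0
    return out


def pi_ratio_z(focal_windows: Sequence[DiversityWindow],
               background_windows: Sequence[DiversityWindow],
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window pi_background / pi_focal and its genome-wide Z-score.

    Window grids must match exactly.  Windows with pi_focal == 0 (or either
    pi missing) get a NaN ratio, are excluded from the Z standardization and
    can never qualify on this statistic.
    """
    if len(focal_windows) != len(background_windows):
        raise GridMismatchError("focal and background window lists differ in length")
    ratios = np.full(len(focal_windows), np.nan)
    for i, (f, b) in enumerate(zip(focal_windows, background_windows)):
        if (f.chrom, f.start, f.end) != (b.chrom, b.start, b.end):
            raise GridMismatchError(
                f"window {i}: {f.chrom}:{f.start}-{f.end} vs "
                f"{b.chrom}:{b.start}-{b.end}")
        if f.theta_pi > 0:
            ratios[i] = b.theta_pi / f.theta_pi
    return ratios, _zscores(ratios)


def fst_z(fst_windows: Sequence[FstWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Per-window FST (negative estimates clamped to 0 before
    standardization) and its genome-wide Z-score."""
    if not len(fst_windows):
        raise ValueError("no FST windows")
    vals = np.array([w.fst for w in fst_windows])
    clamped = np.where(np.isfinite(vals), np.maximum(vals, 0.0), np.nan)
    return clamped, _zscores(clamped)


# ---------------------------------------------------------------------------
# mu statistic
# ---------------------------------------------------------------------------

def _mu_ld_factor(r2: np.ndarray) -> float:
    """LD contrast of a window's r^2 matrix: within-flank vs cross-flank."""
    w = r2.shape[0]
    half = w // 2

    def mean_block(block):
        fin = np.isfinite(block)
        return float(block[fin].mean()) if fin.any() else 0.0

    iu_l = np.triu_indices(half, k=1)
    left = mean_block(r2[:half, :half][iu_l])
    iu_r = np.triu_indices(w - half, k=1)
    right = mean_block(r2[half:, half:][iu_r])
    cross = mean_block(r2[:half, half:])
    return float((left + right) / (2.0 * cross + MU_EPS))


def mu_statistic(table: VariantTable, population: Sequence[str],
                 snp_window: int = 50, derived_is_alt: np.ndarray | None = None,
                 mode: str = "snp", window_bp: int = 10_000,
                 ) -> list[MuWindow]:
    """Composite mu over windows of SNPs segregating in ``population``.

    mode="snp" (default): sliding windows of ``snp_window`` consecutive SNPs
    advancing one SNP at a time.  mode="bp": non-overlapping fixed-bp windows
    of ``window_bp`` (the cited scan's 10-kb setting), using however many
    SNPs fall in each.

    ``derived_is_alt`` is an optional per-table-site polarization (1.0: alt
    derived, 0.0: ref derived, NaN: unpolarizable) from the outgroup; the SFS
    factor then uses derived counts, falling back to minor-allele counts at
    unpolarized sites.
    """
    idx = table.sample_indices(population)
    out: list[MuWindow] = []
    for chrom in pd.unique(table.chrom):
        rows = np.flatnonzero(table.chrom == chrom)
        g = table.gt[np.ix_(rows, idx)]
        ok = g >= 0
        m = 2 * ok.sum(axis=1)
        k = np.where(ok, g, 0).sum(axis=1)
        seg = (k > 0) & (k < m) & (m >= 2)
        rows = rows[seg]
        folded = np.minimum(k[seg], m[seg] - k[seg])
        if derived_is_alt is not None:
            ori = np.asarray(derived_is_alt, dtype=float)[rows]
            kd = np.where(ori == 1.0, k[seg],
                          np.where(ori == 0.0, m[seg] - k[seg], folded))
        else:
            kd = folded
        md = m[seg]
        pos = table.pos[rows]
        gsub = table.gt[np.ix_(rows, idx)]
        r2_all = r2_matrix(gsub) if len(rows) else np.empty((0, 0))
        s_total = len(rows)
        L = table.contigs.get(chrom, int(pos.max()) if s_total else 0)

        if mode == "snp":
            if s_total < snp_window:
                raise WindowError(
                    f"{chrom}: {s_total} SNPs < window of {snp_window}")
            starts = [(i, i + snp_window) for i in range(s_total - snp_window + 1)]
        elif mode == "bp":
            starts = []
            for w0 in range(0, L, window_bp):
                in_w = np.flatnonzero((pos - 1 >= w0) & (pos - 1 < w0 + window_bp))
                if len(in_w) >= 2:
                    starts.append((int(in_w[0]), int(in_w[-1]) + 1))
        else:
            raise ConfigurationError(f"unknown mu window mode {mode!r}")

        for a, b in starts:
            w = b - a
            span = int(pos[b - 1] - pos[a])
            mu_var = span * s_total / (w * L) if L else 0.0
            xi1 = int((kd[a:b] == 1).sum())
            xi_high = int((kd[a:b] == md[a:b] - 1).sum())
            mu_sfs = (xi1 + xi_high) / w
            mu_ld = _mu_ld_factor(r2_all[a:b, a:b])
            out.append(MuWindow(chrom, int(pos[a]), int(pos[b - 1]),
                                mu_var * mu_sfs * mu_ld, mu_var, mu_sfs, mu_ld))
    return out


def mu_top_windows(mu_windows: Sequence[MuWindow], top_frac: float = 0.05,
                   ) -> list[MuWindow]:
    """The ceil(top_frac * n) windows with the highest mu."""
    if not mu_windows:
        return []
    n = int(np.ceil(top_frac * len(mu_windows)))
    return sorted(mu_windows, key=lambda w: -w.mu)[:n]


# ---------------------------------------------------------------------------
# combination, merging, gene overlap
# ---------------------------------------------------------------------------

def assemble_sweep_windows(focal_div: Sequence[DiversityWindow],
                           background_div: Sequence[DiversityWindow],
                           fst_windows: Sequence[FstWindow],
                           mu_windows: Sequence[MuWindow],
                           mu_top: float = 0.05) -> list[SweepWindow]:
    """Join the three statistics onto the shared bp-window grid."""
    ratios, z_pi = pi_ratio_z(focal_div, background_div)
    if len(fst_windows) != len(focal_div):
        raise GridMismatchError("FST windows do not match the diversity grid")
    fst_vals, z_fst = fst_z(fst_windows)
    top = mu_top_windows(mu_windows, mu_top)
    tops_by_chrom: dict[str, np.ndarray] = {}
    for w in top:
        tops_by_chrom.setdefault(w.chrom, [])
    for w in top:
        tops_by_chrom[w.chrom].append(w.midpoint)      # type: ignore[union-attr]
    tops_by_chrom = {c: np.asarray(v) for c, v in tops_by_chrom.items()}
    out = []
    for i, (f, b, w) in enumerate(zip(focal_div, background_div, fst_windows)):
        if (w.chrom, w.start, w.end) != (f.chrom, f.start, f.end):
            raise GridMismatchError(
                f"FST window {i} misaligned with diversity grid")
        mids = tops_by_chrom.get(f.chrom)
        hit = bool(mids is not None
                   and np.any((mids - 1 >= f.start) & (mids - 1 < f.end)))
        out.append(SweepWindow(
            f.chrom, f.start, f.end,
            pi_focal=f.theta_pi, pi_background=b.theta_pi,
            pi_ratio=float(ratios[i]), z_pi=float(z_pi[i]),
            fst=float(fst_vals[i]), z_fst=float(z_fst[i]), mu_hit=hit))
    return out


def candidate_regions(sweep_windows: Sequence[SweepWindow],
                      combine: str = "all", z_min: float = 3.0,
                      at_least: int = 2) -> list[SweepRegion]:
    """Qualify windows per the combine mode and merge into maximal regions.

    combine: "all" (intersection of the three criteria), "any", or
    "at-least-k" (>= ``at_least`` criteria).  Windows are 0-based half-open;
    overlapping or abutting qualifying windows merge.
    """
    if combine not in ("all", "any", "at-least-k"):
        raise ConfigurationError(f"unknown combine mode {combine!r}")
    qualifying = []
    for w in sweep_windows:
        crit = {
            "z_pi": bool(np.isfinite(w.z_pi) and w.z_pi > z_min),
            "z_fst": bool(np.isfinite(w.z_fst) and w.z_fst > z_min),
            "mu": w.mu_hit,
        }
        w.flags = crit
        n = sum(crit.values())
        ok = (n == 3 if combine == "all"
              else n >= 1 if combine == "any"
              else n >= at_least)
        if ok:
            qualifying.append(w)
    regions: list[SweepRegion] = []
    for w in sorted(qualifying, key=lambda w: (w.chrom, w.start)):
        if (regions and regions[-1].chrom == w.chrom
                and w.start <= regions[-1].end):
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.n_windows += 1
            r.criteria = tuple(sorted(set(r.criteria)
                                      | {c for c, v in w.flags.items() if v}))
        else:
            regions.append(SweepRegion(
                w.chrom, w.start, w.end, 1,
                tuple(sorted(c for c, v in w.flags.items() if v))))
    return regions


def read_gff3_genes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((f[0], int(f[3]), int(f[4]),
                         attrs.get("ID", attrs.get("Name", "?"))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def genes_in_regions(regions: Sequence[SweepRegion], genes: pd.DataFrame,
                     ) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp (gene coordinates are
    1-based inclusive, regions 0-based half-open)."""
    for r in regions:
        m = ((genes["chrom"] == r.chrom)
             & (genes["start"] - 1 < r.end)
             & (genes["end"] > r.start))
        r.genes = list(genes.loc[m, "gene_id"])
    return list(regions)


def windows_frame(windows: Sequence[SweepWindow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": w.chrom, "start": w.start, "end": w.end,
        "pi_focal": w.pi_focal, "pi_background": w.pi_background,
        "pi_ratio": w.pi_ratio, "z_pi": w.z_pi, "fst": w.fst,
        "z_fst": w.z_fst, "mu_hit": w.mu_hit} for w in windows])


def regions_bed(regions: Sequence[SweepRegion]) -> str:
    lines = [f"{r.chrom}\t{r.start}\t{r.end}\t{','.join(r.criteria)}\t"
             f"{r.n_windows}" for r in regions]
    return "\n".join(lines) + ("\n" if lines else "")
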