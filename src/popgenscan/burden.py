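"""Outgroup polarization and deleterious-load accounting.

Sites are polarized against a single homozygous outgroup individual: the
allele the outgroup does not carry is the derived allele, and per-sample
genotypes become derived-allele dosages.  Burden arithmetic follows the
standard plant-load convention: a sample's derived-allele total in a class is
2 x (hom-derived sites) + 1 x (het sites), and the normalized burden is the
ratio of deleterious to synonymous derived totals (dSNP/sSNP).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SampleLookupError
from .variantio import MISSING, SiteAnnotation, VariantTable

log = logging.getLogger(__name__)

#: SIFT threshold splitting nonsynonymous sites: < 0.05 deleterious,
#: >= 0.05 tolerant
SIFT_DELETERIOUS = 0.05

BURDEN_CLASSES = ("deleterious", "tolerant", "synonymous", "lof")


@dataclass
class PolarizedMatrix:
    """Derived-allele dosages for outgroup-polarizable sites.

    ``site_index`` maps rows back to the source table; ``dosage`` is
    (n_sites, n_samples) derived dosage with -1 missing; ``excluded`` records
    dropped sites and why (outgroup heterozygous / outgroup missing).
    """
    site_index: np.ndarray
    derived_allele: np.ndarray
    derived_is_alt: np.ndarray
    samples: list[str]
    dosage: np.ndarray
    excluded: pd.DataFrame      # columns chrom, pos, reason

    @property
    def n_sites(self) -> int:
        return len(self.site_index)

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site cohort derived copies k and non-missing copies m."""
        ok = self.dosage >= 0
        m = 2 * ok.sum(axis=1)
        k = np.where(ok, self.dosage, 0).sum(axis=1)
        return k, m


@dataclass
class BurdenProfile:
    sample: str
    hom: dict[str, int]           # class -> hom-derived site count
    het: dict[str, int]
    total: dict[str, int]         # 2*hom + het
    dsnp_ssnp: float              # deleterious total / synonymous total


@dataclass
class ClassSfs:
    site_class: str
    histogram: dict[int, int]     # derived count -> n sites

    @property
    def n_sites(self) -> int:
        return sum(self.histogram.values())

    def proportion_at(self, count: int) -> float:
        n = self.n_sites
        return self.histogram.get(count, 0) / n if n else float("nan")


@dataclass
class PfamBurden:
    pfam_id: str
    mean_dsnp_freq: float
    mean_ssnp_freq: float
    normalized: float             # NaN when no sSNP sites
    top5: bool = False


def polarize(table: VariantTable, outgroup_sample: str) -> PolarizedMatrix:
    """Polarize alleles against the homozygous outgroup.

    Sites where the outgroup is hom-ref keep alt as derived; hom-alt sites
    flip (ref is derived, dosages become 2 - gt).  Outgroup-het and
    outgroup-missing sites are excluded and ledgered.
    """
    j = table.sample_index(outgroup_sample)
    og = table.gt[:, j]
    cohort = [s for s in table.samples if s != outgroup_sample]
    cols = table.sample_indices(cohort)
    g = table.gt[:, cols]

    keep = (og == 0) | (og == 2)
    reason = np.where(og == 1, "outgroup heterozygous", "outgroup missing")
    excluded = pd.DataFrame({
        "chrom": table.chrom[~keep], "pos": table.pos[~keep],
        "reason": reason[~keep]})

    derived_is_alt = og[keep] == 0
    dosage = g[keep].astype(np.int8)
    flip = ~derived_is_alt
    block = dosage[flip]
    miss = block == MISSING
    block = (2 - block).astype(np.int8)
    block[miss] = MISSING
    dosage[flip] = block
    derived_allele = np.where(derived_is_alt, table.alt[keep], table.ref[keep])
    return PolarizedMatrix(
        site_index=np.flatnonzero(keep), derived_allele=derived_allele,
        derived_is_alt=derived_is_alt, samples=cohort, dosage=dosage,
        excluded=excluded)


def derived_orientation(table: VariantTable, outgroup_sample: str) -> np.ndarray:
    """Per-site polarization aligned to the full table: 1.0 where alt is the
    derived allele (outgroup hom-ref), 0.0 where ref is derived (outgroup
    hom-alt), NaN where the outgroup is heterozygous or missing."""
    og = table.gt[:, table.sample_index(outgroup_sample)]
    out = np.full(table.n_sites, np.nan)
    out[og == 0] = 1.0
    out[og == 2] = 0.0
    return out


def classify_sites(ann_rows: pd.DataFrame) -> np.ndarray:
    """Five-way class per annotation row (aligned to a table via
    SiteAnnotation.aligned_to): synonymous / tolerant / deleterious / lof /
    noncoding, with nonsynonymous sites split at SIFT 0.05 (strict <) and
    "high"-effect sites labelled lof regardless of SIFT.  Nonsynonymous rows
    without a SIFT score are excluded (empty label) with a warning.
    """
    effect = ann_rows["effect"].astype(str).to_numpy()
    sift = pd.to_numeric(ann_rows["sift"], errors="coerce").to_numpy()
    out = np.full(len(ann_rows), "", dtype=object)
    out[effect == "synonymous"] = "synonymous"
    out[effect == "noncoding"] = "noncoding"
    out[np.isin(effect, ("high", "lof", "LoF"))] = "lof"
    nonsyn = effect == "nonsynonymous"
    has = nonsyn & np.isfinite(sift)
    out[has & (sift < SIFT_DELETERIOUS)] = "deleterious"
    out[has & (sift >= SIFT_DELETERIOUS)] = "tolerant"
    n_missing = int((nonsyn & ~np.isfinite(sift)).sum())
    if n_missing:
        log.warning("classify_sites: %d nonsynonymous sites without SIFT "
                    "score excluded", n_missing)
    return out


def burden_per_sample(pm: PolarizedMatrix, classes: np.ndarray,
                      ) -> list[BurdenProfile]:
    """Per-sample polarized burden ledger by class and zygosity.

    Missing genotypes contribute nothing.  dSNP/sSNP is NaN for a sample with
    zero synonymous derived alleles.
    """
    profiles = []
    for j, sample in enumerate(pm.samples):
        d = pm.dosage[:, j]
        hom, het, total = {}, {}, {}
        for cls in BURDEN_CLASSES:
            m = classes == cls
            hom[cls] = int(((d == 2) & m).sum())
            het[cls] = int(((d == 1) & m).sum())
            total[cls] = 2 * hom[cls] + het[cls]
        ratio = (total["deleterious"] / total["synonymous"]
                 if total["synonymous"] else float("nan"))
        profiles.append(BurdenProfile(sample, hom, het, total, ratio))
    return profiles


def burden_frame(profiles: list[BurdenProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"sample": p.sample, "dsnp_ssnp": p.dsnp_ssnp}
        for cls in BURDEN_CLASSES:
            row[f"{cls}_hom"] = p.hom[cls]
            row[f"{cls}_het"] = p.het[cls]
            row[f"{cls}_total"] = p.total[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def derived_sfs_by_class(pm: PolarizedMatrix, classes: np.ndarray,
                         ) -> dict[str, ClassSfs]:
    """Histogram of per-site cohort derived-allele counts for each class;
    sites with zero derived copies (fixed ancestral) are dropped."""
    k, _ = pm.derived_counts()
    out = {}
    for cls in sorted(set(classes) - {""}):
        kk = k[(classes == cls) & (k > 0)]
        vals, counts = np.unique(kk, return_counts=True)
        out[cls] = ClassSfs(cls, {int(v): int(c) for v, c in zip(vals, counts)})
    return out


def sfs_frame(sfs: dict[str, ClassSfs]) -> pd.DataFrame:
    rows = [{"class": s.site_class, "derived_count": c, "n_sites": n}
            for s in sfs.values() for c, n in sorted(s.histogram.items())]
    return pd.DataFrame(rows)


def pfam_burden(pm: PolarizedMatrix, classes: np.ndarray,
                pfam_of_site: Sequence[str], top_frac: float = 0.05,
                ) -> list[PfamBurden]:
    """Per-Pfam mean derived frequencies of dSNP and sSNP sites, normalized
    burden (dSNP mean / sSNP mean) and top-5% flags.

    ``pfam_of_site`` aligns to the polarized sites; empty strings are
    unassigned.  The top cut flags the ceil(top_frac * n) highest normalized
    burdens, extending through ties at the boundary; families without sSNP
    sites have undefined burden and are never flagged.
    """
    k, m = pm.derived_counts()
    with np.errstate(invalid="ignore"):
        freq = np.where(m > 0, k / np.maximum(m, 1), np.nan)
    pfam = np.asarray(pfam_of_site, dtype=object)
    out = []
    for pf in sorted({p for p in pfam if p}):
        rows = pfam == pf
        d = freq[rows & (classes == "deleterious")]
        s = freq[rows & (classes == "synonymous")]
        mean_d = float(np.nanmean(d)) if len(d) else float("nan")
        mean_s = float(np.nanmean(s)) if len(s) else float("nan")
        norm = (mean_d / mean_s
                if len(s) and np.isfinite(mean_s) and mean_s > 0
                else float("nan"))
        out.append(PfamBurden(pf, mean_d, mean_s, norm))
    ranked = sorted([p for p in out if np.isfinite(p.normalized)],
                    key=lambda p: -p.normalized)
    n_flag = int(np.ceil(top_frac * len(ranked)))
    if n_flag:
        cut = ranked[n_flag - 1].normalized
        for p in ranked:
            p.top5 = p.normalized >= cut
    return sorted(out, key=lambda p: (-(p.normalized
                                        if np.isfinite(p.normalized)
                                        else -np.inf), p.pfam_id))


def het_fraction_by_class(pm: PolarizedMatrix, classes: np.ndarray,
                          mode: str = "per_sample",
                          ) -> dict[str, float]:
    """Fraction of derived sites that are heterozygous, per class.

    "per_sample" (default): mean over samples of het/(het + hom), samples
    with no derived sites in the class excluded.  "pooled": cohort-wide
    pooled site counts.
    """
    if mode not in ("per_sample", "pooled"):
        raise ValueError("mode must be 'per_sample' or 'pooled'")
    out = {}
    for cls in BURDEN_CLASSES:
        m = classes == cls
        d = pm.dosage[m]
        het = (d == 1).sum(axis=0).astype(float)
        hom = (d == 2).sum(axis=0).astype(float)
        if mode == "pooled":
            tot = het.sum() + hom.sum()
            out[cls] = float(het.sum() / tot) if tot else float("nan")
        else:
            carriers = het + hom > 0
            if carriers.any():
                out[cls] = float((het[carriers]
                                  / (het + hom)[carriers]).mean())
            else:
                out[cls] = float("nan")
    return out


def conservation_rank(gene_snps: Sequence[tuple[str, float, float]],
                      ) -> list[tuple[str, float, float]]:
    """Rank a gene's nonsynonymous SNPs by conservation: ascending SIFT
    (most conserved first), ties broken by smaller association p-value.
    Input tuples are (snp_id, sift, p)."""
    return sorted(gene_snps, key=lambda t: (t[1], t[2]))
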