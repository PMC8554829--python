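"""Variant I/O, hard site filters, MAF filter, and 4-fold-degenerate site extraction.

The in-memory cohort is a :class:`VariantTable`: biallelic SNP sites with the
per-site quality fields used by the hard filter (QUAL, QD, MQ, MQ0, DP) and a
sites x samples genotype matrix coded as alt-allele dosage 0/1/2 with -1 for
missing calls.

Coordinate conventions: VCF and GFF3 are 1-based inclusive on disk; every
internal window or region is 0-based half-open.  Conversions are centralized
in :func:`pos_to_internal` / :func:`internal_to_pos` and nothing else is
allowed to add or subtract 1.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

from .errors import AnnotationError, SampleLookupError, VcfParseError

log = logging.getLogger(__name__)

# genotype codes (alt-allele dosage; -1 = missing)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: default hard-filter thresholds: a site is removed iff
#: QUAL < 30 OR QD < 2 OR MQ < 30 OR MQ0/DP > 0.1
QUAL_MIN = 30.0
QD_MIN = 2.0
MQ_MIN = 30.0
MQ0_DP_MAX = 0.1


def pos_to_internal(pos: int) -> int:
    """1-based inclusive position -> 0-based half-open start coordinate."""
    return pos - 1


def internal_to_pos(start: int) -> int:
    """0-based coordinate -> 1-based position."""
    return start + 1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Biallelic SNP sites x diploid samples.

    ``gt`` holds alt-allele dosages (0 hom-ref, 1 het, 2 hom-alt, -1 missing)
    with shape ``(n_sites, n_samples)``.  ``sample_dp`` is an optional
    per-genotype read-depth matrix of the same shape, carried through VCF
    round trips when present.
    """

    chrom: np.ndarray          # object dtype, per site
    pos: np.ndarray            # int64, 1-based as in VCF
    ref: np.ndarray            # object dtype, single base
    alt: np.ndarray
    qual: np.ndarray           # float64
    qd: np.ndarray
    mq: np.ndarray
    mq0: np.ndarray
    dp: np.ndarray
    samples: list[str]
    gt: np.ndarray             # int8 (n_sites, n_samples)
    contigs: dict[str, int] = field(default_factory=dict)   # name -> length
    sample_dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual", "qd", "mq", "mq0", "dp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has wrong length")
        if self.gt.shape != (n, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.gt, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("genotype matrix contains codes outside {0,1,2,-1}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise SampleLookupError(f"sample {sample!r} not in table") from None

    def sample_indices(self, samples: Sequence[str] | None) -> np.ndarray:
        if samples is None:
            return np.arange(self.n_samples)
        return np.array([self.sample_index(s) for s in samples], dtype=int)

    def take_sites(self, idx: np.ndarray) -> "VariantTable":
        """Subset sites by (sorted) integer or boolean index."""
        return replace(
            self,
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=self.alt[idx], qual=self.qual[idx], qd=self.qd[idx],
            mq=self.mq[idx], mq0=self.mq0[idx], dp=self.dp[idx],
            gt=self.gt[idx],
            sample_dp=None if self.sample_dp is None else self.sample_dp[idx],
        )

    def take_samples(self, samples: Sequence[str]) -> "VariantTable":
        idx = self.sample_indices(samples)
        return replace(
            self, samples=list(samples), gt=self.gt[:, idx],
            sample_dp=None if self.sample_dp is None else self.sample_dp[:, idx],
        )

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites inside a 0-based half-open region."""
        p0 = self.pos - 1
        return (self.chrom == chrom) & (p0 >= start) & (p0 < end)

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing copies (NaN if none)."""
        g = self.gt if sample_idx is None else self.gt[:, sample_idx]
        ok = g >= 0
        copies = 2 * ok.sum(axis=1)
        alt = np.where(ok, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(sample_idx)
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """sample id -> population label, with at most one outgroup sample."""

    assignments: dict[str, str]
    outgroup: str | None = None

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, p in self.assignments.items():
            if s != self.outgroup:
                seen.setdefault(p, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items()
               if p == population and s != self.outgroup]
        if not out:
            raise SampleLookupError(f"population {population!r} has no members")
        return out


def read_population_map(path) -> PopulationMap:
    """TSV with columns sample, population; population 'outgroup' flags the outgroup."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    outgroup = None
    assignments: dict[str, str] = {}
    for s, p in zip(df["sample"], df["population"]):
        assignments[s] = p
        if p.lower() == "outgroup":
            outgroup = s
    return PopulationMap(assignments, outgroup)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in pm.assignments.items():
            fh.write(f"{s}\t{p}\n")


@dataclass
class SiteAnnotation:
    """Per-site functional annotation.

    ``table`` columns: chrom, pos, ref, alt, effect, sift, gene_id, pfam_id.
    ``effect`` is the raw annotation label (synonymous / nonsynonymous / high /
    noncoding); the 5-way class used by the burden analysis is derived from it
    and the SIFT score by :func:`popgenscan.burden.classify_sites`.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "pos", "ref", "alt", "effect", "sift", "gene_id", "pfam_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise AnnotationError(f"annotation table missing columns {missing}")

    def aligned_to(self, vt: VariantTable) -> pd.DataFrame:
        """Annotation rows reindexed to the table's site order (NaN where absent)."""
        key = pd.MultiIndex.from_arrays([vt.chrom, vt.pos])
        idx = self.table.set_index(["chrom", "pos"])
        return idx.reindex(key).reset_index(names=["chrom", "pos"])


def read_annotation(path) -> SiteAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str,
                                            "pfam_id": str})
    return SiteAnnotation(df)


def write_annotation(ann: SiteAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

# with gts012=True, cyvcf2 codes 0/1/2 = hom-ref/het/hom-alt, 3 = unknown
_GT_FROM_CYVCF2 = {0: HOM_REF, 1: HET, 2: HOM_ALT, 3: MISSING}


def read_vcf(path, sample_subset: Sequence[str] | None = None) -> VariantTable:
    """Load biallelic SNP records from a VCF v4.x file.

    Multiallelic records and indels are skipped; the skip counts are logged
    and attached to the returned table as ``skipped_multiallelic`` /
    ``skipped_indel`` attributes.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True,
                  samples=list(sample_subset) if sample_subset else None)
    except Exception as exc:                      # pragma: no cover - cyvcf2 detail
        raise VcfParseError(f"cannot open {path}: {exc}") from exc

    samples = list(vcf.samples)
    contigs: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        contigs[name] = int(length)

    chrom, pos, ref, alt = [], [], [], []
    qual, qd, mq, mq0, dp = [], [], [], [], []
    gts, dps = [], []
    n_multi = n_indel = 0
    lineno = 0
    try:
        for v in vcf:
            lineno += 1
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            if not v.is_snp:
                n_indel += 1
                continue
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0])
            qual.append(np.nan if v.QUAL is None else float(v.QUAL))
            info = v.INFO
            qd.append(float(info.get("QD", np.nan)))
            mq.append(float(info.get("MQ", np.nan)))
            mq0.append(float(info.get("MQ0", np.nan)))
            dp.append(float(info.get("DP", np.nan)))
            gts.append([_GT_FROM_CYVCF2[t] for t in v.gt_types])
            try:
                d = v.format("DP")
            except KeyError:
                d = None
            dps.append(None if d is None else d[:, 0])
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed record at data line {lineno + 1}: {exc}") from exc

    if n_multi or n_indel:
        log.info("read_vcf: skipped %d multiallelic and %d indel records",
                 n_multi, n_indel)
    sample_dp = None
    if dps and all(d is not None for d in dps):
        sample_dp = np.array(dps, dtype=np.int32)
    vt = VariantTable(
        chrom=np.array(chrom, dtype=object), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        qual=np.array(qual), qd=np.array(qd), mq=np.array(mq),
        mq0=np.array(mq0), dp=np.array(dp),
        samples=samples, gt=np.array(gts, dtype=np.int8).reshape(len(pos), len(samples)),
        contigs=contigs, sample_dp=sample_dp,
    )
    vt.skipped_multiallelic = n_multi        # type: ignore[attr-defined]
    vt.skipped_indel = n_indel               # type: ignore[attr-defined]
    return vt


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path) -> None:
    """Write a VCF v4.2 file; bit-stable for a fixed table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgenscan\n")
        for name, length in table.contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with MQ zero">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dp = table.sample_dp is not None
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        fmt = "GT:DP" if has_dp else "GT"
        for i in range(table.n_sites):
            info = (f"QD={table.qd[i]:.2f};MQ={table.mq[i]:.2f};"
                    f"MQ0={table.mq0[i]:.0f};DP={table.dp[i]:.0f}")
            cells = []
            for j in range(table.n_samples):
                g = _GT_STR[int(table.gt[i, j])]
                if has_dp:
                    g = f"{g}:{int(table.sample_dp[i, j])}"
                cells.append(g)
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                     f"{table.alt[i]}\t{table.qual[i]:.2f}\tPASS\t{info}\t{fmt}\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_qual: int
    removed_qd: int
    removed_mq: int
    removed_mq0_dp: int


def filter_sites(table: VariantTable,
                 qual_min: float = QUAL_MIN, qd_min: float = QD_MIN,
                 mq_min: float = MQ_MIN, mq0_dp_max: float = MQ0_DP_MAX,
                 ) -> tuple[VariantTable, FilterReport]:
    """Hard site filter: remove sites with QUAL < 30, QD < 2, MQ < 30 or
    MQ0/DP > 0.1 (defaults).  Boundary values pass: removal criteria are the
    strict inequalities, so QUAL = 30 is retained.

    Returns the filtered table and a per-criterion removal report (a site
    failing several criteria is counted under each).
    """
    for name in ("qual", "qd", "mq", "mq0", "dp"):
        vals = getattr(table, name)
        if np.isnan(vals).any():
            i = int(np.flatnonzero(np.isnan(vals))[0])
            raise AnnotationError(
                f"site {table.chrom[i]}:{table.pos[i]} missing quality field "
                f"{name.upper()}")
    bad_qual = table.qual < qual_min
    bad_qd = table.qd < qd_min
    bad_mq = table.mq < mq_min
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(table.dp > 0, table.mq0 / np.maximum(table.dp, 1e-300), np.inf)
    bad_ratio = ratio > mq0_dp_max
    keep = ~(bad_qual | bad_qd | bad_mq | bad_ratio)
    report = FilterReport(
        n_input=table.n_sites, n_retained=int(keep.sum()),
        removed_qual=int(bad_qual.sum()), removed_qd=int(bad_qd.sum()),
        removed_mq=int(bad_mq.sum()), removed_mq0_dp=int(bad_ratio.sum()),
    )
    return table.take_sites(keep), report


def filter_maf(table: VariantTable, maf_min: float,
               samples: Sequence[str] | None = None) -> VariantTable:
    """Retain sites with minor allele frequency strictly above ``maf_min``.

    The MAF is computed on non-missing allele copies (over ``samples`` if
    given, else the whole cohort).  Monomorphic sites always fail.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    idx = table.sample_indices(samples)
    maf = table.maf(idx)
    keep = np.nan_to_num(maf, nan=0.0) > maf_min
    return table.take_sites(keep)


# ---------------------------------------------------------------------------
# four-fold degenerate sites
# ---------------------------------------------------------------------------

#: codon prefixes whose amino acid is independent of the third base
#: (standard genetic code): the eight 4-fold degenerate codon families
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join((a, b)) for a in "ACGT" for b in "ACGT")
    if len({str(Seq(p + t).translate()) for t in "ACGT"}) == 1
)


def _parse_gff3_cds(path) -> dict[str, list[tuple[str, int, int, str, int]]]:
    """Group CDS features by transcript: parent -> [(chrom, start1, end1, strand, phase)]."""
    by_tx: dict[str, list[tuple[str, int, int, str, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent", attrs.get("ID", "?"))
            phase = int(f[7]) if f[7] in "012" else 0
            by_tx.setdefault(parent, []).append(
                (f[0], int(f[3]), int(f[4]), f[6], phase))
    return by_tx


def identify_4dtv_sites(fasta_path, gff3_path) -> set[tuple[str, int]]:
    """Genomic positions (1-based) at third codon positions of four-fold
    degenerate codons, strand aware, under the standard genetic code.

    With overlapping CDS from alternative transcripts, a position is reported
    only if it is four-fold degenerate in *every* transcript whose CDS covers
    it.  Transcripts whose CDS length is not a multiple of 3 after phase
    adjustment are skipped with a warning.
    """
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    fourfold: set[tuple[str, int]] = set()
    covered_bad: set[tuple[str, int]] = set()

    for tx, parts in _parse_gff3_cds(gff3_path).items():
        strand = parts[0][3]
        parts = sorted(parts, key=lambda p: p[1])
        coords: list[tuple[str, int]] = []       # transcript order, 1-based
        for chrom_, s, e, _, _ in parts:
            coords.extend((chrom_, p) for p in range(s, e + 1))
        if strand == "-":
            coords = coords[::-1]
            first_phase = sorted(parts, key=lambda p: p[1])[-1][4]
        else:
            first_phase = parts[0][4]
        coords = coords[first_phase:]
        if len(coords) % 3 != 0:
            log.warning("CDS of %s not divisible by 3 after phase; skipped", tx)
            continue
        tx_four: set[tuple[str, int]] = set()
        for i in range(0, len(coords), 3):
            triple = coords[i:i + 3]
            bases = []
            ok = True
            for chrom_, p in triple:
                seq = genome.get(chrom_)
                if seq is None or not 1 <= p <= len(seq):
                    ok = False
                    break
                bases.append(seq[p - 1])
            if not ok:
                continue
            codon = "".join(bases)
            if strand == "-":
                codon = str(Seq(codon).complement())
            if codon[:2] in FOURFOLD_PREFIXES:
                tx_four.add(triple[2])
        # conservative intersection across transcripts covering a position
        for pos in (set(coords) - tx_four):
            covered_bad.add(pos)
        fourfold |= tx_four
    return fourfold - covered_bad
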