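"""Synthetic multi-population diploid SNP cohorts with full ground truth.

The generator emulates the study design the downstream scans are built for: a
handful of diverged populations (one optionally bottlenecked), a single fully
homozygous outgroup individual for allele polarization, functional site
classes (synonymous / tolerant / deleterious / LoF / noncoding) in which the
deleterious classes segregate at suppressed frequencies, and optional injected
hard sweeps.

Engine
------
A frequency-level Wright-Fisher simulator.  Segregating sites are initialised
from the stationary frequency spectrum of the WF diffusion on a notional pool
of ``pool_size`` haplotypes: density proportional to 1/q for neutral classes
and Wright's selection form

    f(q)  proportional to  (1 - exp(-2*gamma*(1-q))) / (q*(1-q)),   gamma = -2*Ne*s

for the deleterious and LoF classes (multiplicative fitness 1-s per derived
copy).  Population allele frequencies then drift along the population tree by
discrete-generation binomial resampling with a deterministic selection step,
rescaled to ``drift_size`` diploids holding 2*N*s, t/(2*N) and 4*N*mu fixed;
new mutations enter each lineage at the rescaled rate.  Sampled genotypes are
drawn exactly (hypergeometric from the pool when there is no drift phase,
binomial otherwise) and derived alleles are placed on haplotypes through a
copying process whose along-chromosome switch rate is proportional to
4*Ne*rho, which produces distance-dependent LD: rho = 0 gives complete
linkage, larger rho gives faster r^2 decay.

Everything flows from one :class:`numpy.random.Generator` seeded with the
single config seed, so all outputs are bit-reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RegionError, SampleLookupError
from .variantio import (MISSING, PopulationMap, SiteAnnotation, VariantTable,
                        write_annotation, write_population_map, write_vcf)

log = logging.getLogger(__name__)

OUTGROUP_NAME = "outgroup"
CLASSES = ("synonymous", "tolerant", "deleterious", "lof")
#: raw annotation effect labels written to the TSV (classify_sites re-derives
#: the 5-way class from these plus the SIFT score)
EFFECT_OF_CLASS = {"synonymous": "synonymous", "tolerant": "nonsynonymous",
                   "deleterious": "nonsynonymous", "lof": "high",
                   "noncoding": "noncoding"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """A hard sweep to inject: ``chrom`` (name), bp ``center``, final frequency
    of the beneficial haplotype in the focal population, and interval
    half-width (the hitchhiking footprint)."""
    chrom: str
    center: int
    final_freq: float
    focal_pop: str
    half_width: int = 40_000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pops: int = 3
    samples_per_pop: tuple[int, ...] = (20, 20, 20)
    Ne: float = 10_000.0
    #: generations ago; element j is when population j split from j+1..;
    #: length n_pops - 1, non-increasing
    split_times: tuple[float, ...] = (7_000.0, 3_000.0)
    #: (population index, start generation ago, size factor) or None
    bottleneck: tuple[int, float, float] | None = (1, 3_000.0, 0.2)
    mu: float = 2.5e-9          # per bp per generation
    rho: float = 1.0e-8         # per bp per generation
    L: int = 1_000_000          # per-chromosome length, bp
    n_chrom: int = 1
    frac_synonymous: float = 0.40
    frac_tolerant: float = 0.30
    frac_deleterious: float = 0.25
    frac_lof: float = 0.05
    #: fitness cost per derived allele copy at deleterious / LoF sites
    sel_coeff_deleterious: float = 2.5e-4
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.02
    #: haplotypes in the stationary-spectrum pool
    pool_size: int = 400
    #: diploid size of the rescaled drift stage
    drift_size: int = 200
    #: gene model layout: single-exon CDS of gene_length bp every gene_period bp
    gene_length: int = 3_000
    gene_period: int = 4_000
    n_pfams: int = 40

    def validate(self) -> None:
        def positive(name):
            v = getattr(self, name)
            if not np.all(np.asarray(v, dtype=float) > 0):
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_pops < 1:
            raise ConfigurationError("n_pops must be >= 1")
        if len(self.samples_per_pop) != self.n_pops:
            raise ConfigurationError(
                "samples_per_pop length must equal n_pops")
        for name in ("samples_per_pop", "Ne", "mu", "L", "n_chrom",
                     "pool_size", "drift_size", "gene_length", "gene_period"):
            positive(name)
        if self.rho < 0:
            raise ConfigurationError("rho must be >= 0")
        if len(self.split_times) != self.n_pops - 1:
            raise ConfigurationError(
                "split_times length must equal n_pops - 1")
        if any(t <= 0 for t in self.split_times):
            raise ConfigurationError("split_times must be strictly positive")
        if any(a < b for a, b in zip(self.split_times, self.split_times[1:])):
            raise ConfigurationError("split_times must be non-increasing")
        fr = (self.frac_synonymous + self.frac_tolerant
              + self.frac_deleterious + self.frac_lof)
        if abs(fr - 1.0) > 1e-9:
            raise ConfigurationError(
                f"frac_synonymous/tolerant/deleterious/lof sum to {fr}, not 1")
        if self.sel_coeff_deleterious < 0:
            raise ConfigurationError("sel_coeff_deleterious must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.bottleneck is not None:
            pop, start, factor = self.bottleneck
            if not 0 <= int(pop) < self.n_pops:
                raise ConfigurationError("bottleneck population out of range")
            if start <= 0 or factor <= 0:
                raise ConfigurationError(
                    "bottleneck start generation and size factor must be > 0")
        if self.pool_size <= 2 * (max(self.samples_per_pop) + 1):
            raise ConfigurationError(
                "pool_size must exceed twice the largest sample size")
        for sw in self.sweeps:
            if not 0 < sw.final_freq <= 1:
                raise ConfigurationError("sweeps: final_freq must be in (0, 1]")
            if not 1 <= sw.center <= self.L:
                raise ConfigurationError("sweeps: center outside [1, L]")

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    def chrom_names(self) -> list[str]:
        return [f"chr{c + 1}" for c in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""
    site_class: np.ndarray                 # per emitted site
    derived_is_alt: np.ndarray             # bool per site
    derived_allele: np.ndarray             # base per site
    sweeps: dict[str, list[tuple[int, int, str, float]]]   # chrom -> (start1, end1, pop, freq)
    theta_expected: dict[str, float]       # pop -> 4*Ne*mu
    sample_map: dict[str, str]             # sample -> population (outgroup included)
    genes: pd.DataFrame                    # chrom,start,end,strand,gene_id,pfam_id
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "site_class": [str(c) for c in self.site_class],
            "derived_is_alt": [bool(b) for b in self.derived_is_alt],
            "derived_allele": [str(a) for a in self.derived_allele],
            "sweeps": self.sweeps,
            "theta_expected": self.theta_expected,
            "sample_map": self.sample_map,
            "genes": self.genes.to_dict(orient="list"),
            "config": {**asdict(self.config),
                       "sweeps": [asdict(s) for s in self.config.sweeps]},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# gene layout and reference sequence
# ---------------------------------------------------------------------------

def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Regular single-exon gene models: CDS of gene_length bp every
    gene_period bp, strands alternating, Pfam ids drawn from a pool."""
    rows = []
    for chrom in config.chrom_names():
        i = 0
        start = 1001
        while start + config.gene_length - 1 <= config.L - 1000:
            gid = f"g_{chrom}_{i + 1}"
            pfam = f"PF{int(rng.integers(config.n_pfams)) + 1:05d}"
            rows.append((chrom, start, start + config.gene_length - 1,
                         "+" if i % 2 == 0 else "-", gid, pfam))
            i += 1
            start += config.gene_period
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "pfam_id"])


def _chrom_seq(config: SimulationConfig, chrom_idx: int) -> np.ndarray:
    """Deterministic random reference sequence (array of S1 bytes)."""
    rng = np.random.default_rng([config.seed % (2**31), 0xFA57A, chrom_idx])
    return _BASES[rng.integers(0, 4, size=config.L)]


def _cds_fraction(config: SimulationConfig, genes: pd.DataFrame) -> float:
    total = config.L * config.n_chrom
    return float((genes["end"] - genes["start"] + 1).sum()) / total


def _draw_positions(n: int, genes: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator, in_cds: bool) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (chrom, pos) uniformly inside (or outside) CDS intervals."""
    if in_cds:
        g = genes.sample(n=n, replace=True,
                         random_state=np.random.RandomState(rng.integers(2**31)))
        offs = rng.integers(0, config.gene_length, size=n)
        return g["chrom"].to_numpy(), g["start"].to_numpy() + offs
    # complement intervals are the leading/trailing margins plus the
    # inter-gene gaps; the layout is regular so rejection sampling is cheap
    chroms = np.array(config.chrom_names(), dtype=object)
    out_c = np.empty(n, dtype=object)
    out_p = np.empty(n, dtype=np.int64)
    got = 0
    cds_by_chrom = {c: genes[genes["chrom"] == c] for c in chroms}
    while got < n:
        m = (n - got) * 2 + 8
        cc = chroms[rng.integers(0, len(chroms), size=m)]
        pp = rng.integers(1, config.L + 1, size=m)
        for c, p in zip(cc, pp):
            g = cds_by_chrom[c]
            inside = ((g["start"] <= p) & (p <= g["end"])).any()
            if not inside:
                out_c[got] = c
                out_p[got] = p
                got += 1
                if got == n:
                    break
    return out_c, out_p


# ---------------------------------------------------------------------------
# stationary spectrum and drift
# ---------------------------------------------------------------------------

def _stationary_weights(K: int, gamma: float) -> np.ndarray:
    """Expected relative site counts at pool derived counts 1..K-1.

    Neutral (gamma == 0): 1/i.  Otherwise Wright's stationary density for
    genic selection, normalised so it reduces to 1/i as gamma -> 0.
    """
    i = np.arange(1, K)
    q = i / K
    if gamma == 0.0:
        return 1.0 / i
    num = -np.expm1(-2.0 * gamma * (1.0 - q))
    den = -np.expm1(-2.0 * gamma)
    return (num / den) / (q * (1.0 - q)) / K


@dataclass
class _Registry:
    """Growing per-site record shared by all lineages."""
    chrom: list = field(default_factory=list)
    pos: list = field(default_factory=list)
    cls: list = field(default_factory=list)

    def add(self, chrom, pos, cls) -> np.ndarray:
        start = len(self.pos)
        self.chrom.extend(chrom)
        self.pos.extend(int(p) for p in pos)
        self.cls.extend(cls)
        return np.arange(start, len(self.pos))

    def selected_mask(self, ids: np.ndarray) -> np.ndarray:
        cls = np.asarray(self.cls, dtype=object)[ids]
        return (cls == "deleterious") | (cls == "lof")


def _draw_new_site_classes(n: int, config: SimulationConfig, p_cds: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Class labels for newly arising mutations (influx proportional to
    genomic target size)."""
    probs = np.array([
        p_cds * config.frac_synonymous, p_cds * config.frac_tolerant,
        p_cds * config.frac_deleterious, p_cds * config.frac_lof,
        1.0 - p_cds,
    ])
    labels = np.array(list(CLASSES) + ["noncoding"], dtype=object)
    return labels[rng.choice(len(labels), size=n, p=probs / probs.sum())]


def _inject_mutations(n: int, config: SimulationConfig, genes: pd.DataFrame,
                      p_cds: float, rng: np.random.Generator,
                      registry: _Registry) -> np.ndarray:
    cls = _draw_new_site_classes(n, config, p_cds, rng)
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    genic = cls != "noncoding"
    if genic.any():
        c, p = _draw_positions(int(genic.sum()), genes, config, rng, in_cds=True)
        chrom[genic], pos[genic] = c, p
    if (~genic).any():
        c, p = _draw_positions(int((~genic).sum()), genes, config, rng, in_cds=False)
        chrom[~genic], pos[~genic] = c, p
    return registry.add(chrom, pos, cls)


def _drift_epoch(freq: np.ndarray, ids: np.ndarray, gens_real: float,
                 n_real: float, config: SimulationConfig,
                 genes: pd.DataFrame, p_cds: float,
                 rng: np.random.Generator, registry: _Registry,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Drift one lineage for ``gens_real`` generations at diploid size
    ``n_real``, rescaled to ``drift_size`` simulated diploids."""
    n_sim = config.drift_size
    lam = n_real / n_sim                      # rescaling factor
    gens_sim = int(round(gens_real / lam))
    if gens_sim == 0:
        return freq, ids
    s_sim = min(config.sel_coeff_deleterious * lam, 0.5)
    influx = 2.0 * n_real * config.mu * config.L * config.n_chrom
    two_n = 2 * n_sim
    sel = registry.selected_mask(ids)
    for _ in range(gens_sim):
        if s_sim > 0 and sel.any():
            p = freq[sel]
            freq[sel] = p * (1 - s_sim) / (1 - p * s_sim)
        freq = rng.binomial(two_n, freq) / two_n
        n_new = rng.poisson(influx)
        if n_new:
            new_ids = _inject_mutations(n_new, config, genes, p_cds, rng, registry)
            freq = np.concatenate([freq, np.full(n_new, 1.0 / two_n)])
            ids = np.concatenate([ids, new_ids])
            sel = np.concatenate([sel, registry.selected_mask(new_ids)])
        # prune sites lost in this lineage to keep the arrays bounded
        if len(freq) > 50_000:
            keep = freq > 0
            freq, ids, sel = freq[keep], ids[keep], sel[keep]
    return freq, ids


def _simulate_tree(freq_anc: np.ndarray, ids_anc: np.ndarray,
                   config: SimulationConfig, genes: pd.DataFrame, p_cds: float,
                   rng: np.random.Generator, registry: _Registry,
                   ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Chain-topology drift: lineage {j..n-1} splits at split_times[j] into
    {j} and {j+1..n-1}.  Returns per-population (freq, registry ids)."""
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def terminal(pop: int, freq: np.ndarray, ids: np.ndarray, t_from: float):
        epochs: list[tuple[float, float]] = []    # (gens, diploid size)
        bn = config.bottleneck
        if bn is not None and int(bn[0]) == pop and bn[1] < t_from:
            epochs.append((t_from - bn[1], config.Ne))
            epochs.append((bn[1], config.Ne * bn[2]))
        else:
            epochs.append((t_from, config.Ne))
        for gens, size in epochs:
            freq, ids = _drift_epoch(freq, ids, gens, size, config, genes,
                                     p_cds, rng, registry)
        out[pop] = (freq, ids)

    def walk(pops: list[int], freq: np.ndarray, ids: np.ndarray, t_from: float):
        if len(pops) == 1:
            terminal(pops[0], freq, ids, t_from)
            return
        t_split = config.split_times[pops[0]]
        freq, ids = _drift_epoch(freq, ids, t_from - t_split, config.Ne,
                                 config, genes, p_cds, rng, registry)
        walk([pops[0]], freq.copy(), ids.copy(), t_split)
        walk(pops[1:], freq, ids, t_split)

    root_time = config.split_times[0] if config.n_pops > 1 else 0.0
    walk(list(range(config.n_pops)), freq_anc, ids_anc, root_time)
    return out


# ---------------------------------------------------------------------------
# haplotype placement (LD structure)
# ---------------------------------------------------------------------------

def _place_alleles(pos: np.ndarray, counts: np.ndarray, m_h: int,
                   switch_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Place per-site derived counts onto m_h haplotypes.

    A per-haplotype rank variable is redrawn along the chromosome with
    probability 1-exp(-switch_rate * distance); each site's derived alleles go
    to the top-k ranks.  Marginally every k-subset is exchangeable, while
    nearby sites share carriers, producing LD that decays with distance at a
    scale set by switch_rate (complete linkage when switch_rate == 0).
    """
    n = len(pos)
    H = np.zeros((n, m_h), dtype=bool)
    u = rng.random(m_h)
    last = None
    for t in range(n):
        if last is not None and switch_rate > 0:
            c = -np.expm1(-switch_rate * (pos[t] - last))
            redraw = rng.random(m_h) < c
            if redraw.any():
                u[redraw] = rng.random(int(redraw.sum()))
        last = pos[t]
        k = int(counts[t])
        if k >= m_h:
            H[t] = True
        elif k > 0:
            idx = np.argpartition(u, m_h - k)[m_h - k:]
            H[t, idx] = True
    return H


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[VariantTable, SiteAnnotation, SimTruth]:
    """Generate a cohort: genotype table, per-site annotation, ground truth.

    Deterministic for a fixed ``config.seed``.  The last sample is the
    homozygous outgroup individual (named ``outgroup``), which carries the
    ancestral allele at every site and never has missing genotypes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_layout(config, rng)
    p_cds = _cds_fraction(config, genes)
    registry = _Registry()

    # --- ancestral stationary sites -------------------------------------
    K = config.pool_size
    theta = 4.0 * config.Ne * config.mu
    L_tot = config.L * config.n_chrom
    gamma_sel = -2.0 * config.Ne * config.sel_coeff_deleterious
    w_neu = _stationary_weights(K, 0.0)
    w_sel = _stationary_weights(K, gamma_sel)
    class_fracs = {
        "synonymous": p_cds * config.frac_synonymous,
        "tolerant": p_cds * config.frac_tolerant,
        "deleterious": p_cds * config.frac_deleterious,
        "lof": p_cds * config.frac_lof,
        "noncoding": 1.0 - p_cds,
    }
    anc_ids_parts, anc_counts_parts = [], []
    for cls, frac in class_fracs.items():
        w = w_sel if cls in ("deleterious", "lof") else w_neu
        lam = theta * L_tot * frac * w
        n_i = rng.poisson(lam)                       # sites per pool count i
        total = int(n_i.sum())
        if total == 0:
            continue
        pool_counts = np.repeat(np.arange(1, K), n_i)
        in_cds = cls != "noncoding"
        chrom, pos = _draw_positions(total, genes, config, rng, in_cds=in_cds)
        ids = registry.add(chrom, pos, [cls] * total)
        anc_ids_parts.append(ids)
        anc_counts_parts.append(pool_counts)
    anc_ids = (np.concatenate(anc_ids_parts) if anc_ids_parts
               else np.empty(0, dtype=int))
    anc_pool = (np.concatenate(anc_counts_parts) if anc_counts_parts
                else np.empty(0, dtype=int))

    pop_names = config.pop_names
    m_h = [2 * s for s in config.samples_per_pop]

    # --- drift (if any) and per-population sample counts ----------------
    no_drift = config.n_pops == 1 and config.bottleneck is None
    reg_size = None
    counts_by_pop: dict[int, np.ndarray] = {}
    if no_drift:
        reg_size = len(registry.pos)
        k = rng.hypergeometric(anc_pool, K - anc_pool, m_h[0])
        counts = np.zeros(reg_size, dtype=np.int64)
        counts[anc_ids] = k
        counts_by_pop[0] = counts
    else:
        freq_anc = anc_pool / K
        per_pop = _simulate_tree(freq_anc, anc_ids, config, genes, p_cds,
                                 rng, registry)
        reg_size = len(registry.pos)
        for p in range(config.n_pops):
            freq, ids = per_pop[p]
            counts = np.zeros(reg_size, dtype=np.int64)
            counts[ids] = rng.binomial(m_h[p], freq)
            counts_by_pop[p] = counts

    # --- assemble the site table ----------------------------------------
    chrom_arr = np.asarray(registry.chrom, dtype=object)
    pos_arr = np.asarray(registry.pos, dtype=np.int64)
    cls_arr = np.asarray(registry.cls, dtype=object)
    any_derived = np.zeros(reg_size, dtype=bool)
    for p in range(config.n_pops):
        any_derived |= counts_by_pop[p] > 0
    keep = any_derived
    order = np.lexsort((pos_arr, chrom_arr.astype(str)))
    order = order[keep[order]]
    # drop duplicate positions (keep first occurrence)
    key = np.array([f"{chrom_arr[i]}:{pos_arr[i]}" for i in order])
    _, first = np.unique(key, return_index=True)
    order = order[np.sort(first)]

    chrom_s = chrom_arr[order]
    pos_s = pos_arr[order]
    cls_s = cls_arr[order]
    n_sites = len(order)

    # reference/derived alleles: ref base comes from the (deterministic)
    # genome sequence; with probability 0.2 the reference carries the derived
    # allele, exercising the polarity-flip path downstream
    chrom_names = config.chrom_names()
    seqs = {c: _chrom_seq(config, i) for i, c in enumerate(chrom_names)}
    ref = np.array([seqs[c][p - 1].decode() for c, p in zip(chrom_s, pos_s)],
                   dtype=object)
    other = np.array(["ACGT"[(("ACGT".index(r)) + int(j)) % 4]
                      for r, j in zip(ref, rng.integers(1, 4, size=n_sites))],
                     dtype=object)
    ref_is_derived = rng.random(n_sites) < 0.2
    derived_is_alt = ~ref_is_derived
    derived_allele = np.where(derived_is_alt, other, ref)

    # --- genotypes: place derived alleles on haplotypes ------------------
    samples: list[str] = []
    for p, name in enumerate(pop_names):
        samples += [f"{name}_{j + 1:03d}" for j in range(config.samples_per_pop[p])]
    samples.append(OUTGROUP_NAME)
    n_cohort = len(samples) - 1
    gt_derived = np.zeros((n_sites, n_cohort), dtype=np.int8)

    bn = config.bottleneck
    col = 0
    for p in range(config.n_pops):
        factor = bn[2] if (bn is not None and int(bn[0]) == p) else 1.0
        switch = 4.0 * config.Ne * factor * config.rho
        k_pop = counts_by_pop[p][order]
        for ci, cname in enumerate(chrom_names):
            m = chrom_s == cname
            H = _place_alleles(pos_s[m], k_pop[m], m_h[p], switch, rng)
            gt_derived[np.flatnonzero(m)[:, None],
                       col + np.arange(config.samples_per_pop[p])] = (
                H[:, 0::2].astype(np.int8) + H[:, 1::2].astype(np.int8))
        col += config.samples_per_pop[p]

    # alt-allele dosage; outgroup homozygous ancestral
    gt = np.where(derived_is_alt[:, None], gt_derived, 2 - gt_derived
                  ).astype(np.int8)
    og = np.where(derived_is_alt, 0, 2).astype(np.int8)
    gt = np.column_stack([gt, og])

    # missing genotypes: cohort only, never the outgroup
    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_cohort)) < config.missing_rate
        gt[:, :n_cohort][miss] = MISSING

    # --- site quality fields (all plausible pass values) ------------------
    qual = rng.uniform(50, 2000, n_sites).round(2)
    dp_site = rng.poisson(20.0 * len(samples), n_sites).astype(float)
    qd = rng.uniform(15, 35, n_sites).round(2)
    mq = rng.uniform(40, 60, n_sites).round(2)
    mq0 = rng.binomial(np.maximum(dp_site.astype(int), 1), 0.002).astype(float)
    sample_dp = rng.poisson(20.0, (n_sites, len(samples))).astype(np.int32)

    table = VariantTable(
        chrom=chrom_s, pos=pos_s, ref=ref,
        alt=np.where(derived_is_alt, derived_allele, other),
        qual=qual, qd=qd, mq=mq, mq0=mq0, dp=dp_site,
        samples=samples, gt=gt,
        contigs={c: config.L for c in chrom_names},
        sample_dp=sample_dp,
    )

    # --- annotation -------------------------------------------------------
    sift = np.full(n_sites, np.nan)
    low = np.isin(cls_s.astype(str), ("deleterious", "lof"))
    high = np.isin(cls_s.astype(str), ("synonymous", "tolerant"))
    sift[low] = rng.uniform(0.0, 0.05, int(low.sum()))
    sift[high] = rng.uniform(0.05, 1.0, int(high.sum()))
    gene_id = np.full(n_sites, "", dtype=object)
    pfam_id = np.full(n_sites, "", dtype=object)
    for c, g in genes.groupby("chrom", sort=False):
        m = chrom_s == c
        if not m.any():
            continue
        idx = np.searchsorted(g["start"].to_numpy(), pos_s[m], side="right") - 1
        ok = (idx >= 0) & (pos_s[m] <= g["end"].to_numpy()[np.clip(idx, 0, None)])
        rows = np.flatnonzero(m)[ok]
        gene_id[rows] = g["gene_id"].to_numpy()[idx[ok]]
        pfam_id[rows] = g["pfam_id"].to_numpy()[idx[ok]]
    ann = SiteAnnotation(pd.DataFrame({
        "chrom": chrom_s.astype(str), "pos": pos_s,
        "ref": ref.astype(str), "alt": table.alt.astype(str),
        "effect": [EFFECT_OF_CLASS[c] for c in cls_s],
        "sift": sift, "gene_id": gene_id.astype(str),
        "pfam_id": pfam_id.astype(str),
    }))

    sample_map = {s: pop_names[p]
                  for p in range(config.n_pops)
                  for s in samples if s.startswith(pop_names[p] + "_")}
    sample_map[OUTGROUP_NAME] = "outgroup"
    truth = SimTruth(
        site_class=cls_s, derived_is_alt=derived_is_alt,
        derived_allele=derived_allele,
        sweeps={}, theta_expected={n: theta for n in pop_names},
        sample_map=sample_map, genes=genes, config=config,
    )

    for sw in config.sweeps:
        table, truth = inject_sweep(table, truth, sw,
                                    rng=np.random.default_rng(rng.integers(2**31)))
    return table, ann, truth


def inject_sweep(table: VariantTable, truth: SimTruth, sweep: SweepSpec,
                 rng: np.random.Generator | int | None = None,
                 ) -> tuple[VariantTable, SimTruth]:
    """Overwrite haplotypes in the sweep interval of the focal population.

    Each focal haplotype is independently replaced, with probability
    ``final_freq``, by one template (beneficial) haplotype, so the template
    reaches the configured final frequency in expectation and within-interval
    diversity collapses as final_freq -> 1.  Missing genotypes stay missing.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cfg = truth.config
    if sweep.chrom not in table.contigs:
        raise RegionError(f"sweep chromosome {sweep.chrom!r} not in table")
    L = table.contigs[sweep.chrom]
    if not 1 <= sweep.center <= L:
        raise RegionError(
            f"sweep center {sweep.center} outside [1, {L}] on {sweep.chrom}")
    focal = [s for s, p in truth.sample_map.items() if p == sweep.focal_pop]
    if not focal:
        raise SampleLookupError(f"focal population {sweep.focal_pop!r} unknown")

    start1 = max(1, sweep.center - sweep.half_width)
    end1 = min(L, sweep.center + sweep.half_width)
    site_m = table.sites_in(sweep.chrom, start1 - 1, end1)
    sidx = np.flatnonzero(site_m)
    cols = table.sample_indices(focal)
    gt = table.gt.copy()
    if len(sidx):
        sub = gt[np.ix_(sidx, cols)]
        miss = sub == MISSING
        # explode dosages into haplotypes (het phase is arbitrary)
        h1 = (sub >= 1).astype(np.int8)
        h2 = (sub == 2).astype(np.int8)
        flip = rng.random(sub.shape) < 0.5
        h1_, h2_ = np.where(flip, h2, h1), np.where(flip, h1, h2)
        haps = np.empty((len(sidx), 2 * len(cols)), dtype=np.int8)
        haps[:, 0::2], haps[:, 1::2] = h1_, h2_
        # template: the haplotype of the individual with fewest missing sites
        tmpl_ind = int(np.argmin(miss.sum(axis=0)))
        template = haps[:, 2 * tmpl_ind].copy()
        if miss[:, tmpl_ind].any():
            maj = np.round(np.where(miss, np.nan, sub).sum(axis=1)
                           / np.maximum((~miss).sum(axis=1), 1) / 2.0)
            template[miss[:, tmpl_ind]] = maj[miss[:, tmpl_ind]].astype(np.int8)
        swept = rng.random(2 * len(cols)) < sweep.final_freq
        haps[:, swept] = template[:, None]
        new = haps[:, 0::2] + haps[:, 1::2]
        new[miss] = MISSING
        gt[np.ix_(sidx, cols)] = new

    new_table = replace(table, gt=gt)
    sweeps = {k: list(v) for k, v in truth.sweeps.items()}
    sweeps.setdefault(sweep.chrom, []).append(
        (int(start1), int(end1), sweep.focal_pop, float(sweep.final_freq)))
    new_truth = replace(truth, sweeps=sweeps)
    return new_table, new_truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(config: SimulationConfig, table: VariantTable, path) -> None:
    """Reference genome consistent with the table's REF alleles."""
    with open(path, "w") as fh:
        for i, c in enumerate(config.chrom_names()):
            seq = _chrom_seq(config, i).copy()
            m = table.chrom == c
            seq[table.pos[m] - 1] = np.frombuffer(
                "".join(table.ref[m]).encode(), dtype="S1")
            fh.write(f">{c}\n")
            s = seq.tobytes().decode()
            for j in range(0, len(s), 60):
                fh.write(s[j:j + 60] + "\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            base = f"{r.chrom}\tpopgenscan\t"
            attrs = f"ID={r.gene_id}"
            fh.write(f"{base}gene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n")
            fh.write(f"{base}mRNA\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                     f"ID={r.gene_id}.t1;Parent={r.gene_id}\n")
            fh.write(f"{base}CDS\t{r.start}\t{r.end}\t.\t{r.strand}\t0\t"
                     f"ID={r.gene_id}.cds;Parent={r.gene_id}.t1\n")


def write_cohort(table: VariantTable, ann: SiteAnnotation, truth: SimTruth,
                 outdir) -> dict[str, str]:
    """Write VCF, FASTA, GFF3, annotation TSV, population map and truth JSON."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "vcf": "cohort.vcf", "fasta": "genome.fa", "gff3": "genes.gff3",
        "annotation": "annotation.tsv", "popmap": "populations.tsv",
        "truth": "truth.json"}.items()}
    write_vcf(table, paths["vcf"])
    write_fasta(truth.config, table, paths["fasta"])
    write_gff3(truth.genes, paths["gff3"])
    write_annotation(ann, paths["annotation"])
    write_population_map(
        PopulationMap(truth.sample_map, outgroup=OUTGROUP_NAME), paths["popmap"])
    truth.to_json(paths["truth"])
    return paths
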