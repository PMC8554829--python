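# Methods

This note documents the models, estimators and design choices behind
popgenscan, in the order the pipeline runs them.

## Synthetic cohorts

### What the generator emulates

A resequencing cohort of a few diverged diploid populations of a perennial
outcrossing species: an ancestral population at mutation–drift equilibrium
splits along a chain topology (population *j* separates from populations
*j+1…* at `split_times[j]` generations before present), one derived
population may pass through a bottleneck, and one additional individual — the
outgroup — is homozygous for the ancestral allele at every site. Sites carry
functional classes (synonymous, nonsynonymous-tolerant,
nonsynonymous-deleterious, loss-of-function, noncoding); the deleterious and
LoF classes segregate at suppressed frequencies because each derived copy
costs fitness 1−s. Hard sweeps can be injected at chosen positions.

### Engine

A full individual-based forward simulation at realistic Ne needs on the
order of 10·Ne burn-in generations; the generator instead works at the level
of population allele frequencies, which is exact in the diffusion limit the
classical estimators are derived under:

1. **Stationary initialization.** Segregating sites are drawn from the
   stationary frequency spectrum of the Wright–Fisher diffusion on a notional
   pool of K = `pool_size` haplotypes. For neutral classes the expected
   number of sites at pool count *i* is θLf_c/i (θ = 4Neμ, f_c the class's
   genomic fraction); for selected classes the 1/q density is replaced by
   Wright's form (1 − e^(−2γ(1−q)))/(q(1−q)), normalized to reduce to 1/q as
   γ = −2Ne·s → 0. Counts are Poisson, which matches the Poisson Random
   Field picture of independent sites.
2. **Drift.** Along each branch of the population tree, frequencies evolve
   by discrete-generation binomial resampling in a rescaled population of
   `drift_size` diploids: 2Ns, t/2N and 4Nμ are held fixed, so a branch of
   T real generations at size N becomes T·(drift_size/N) simulated
   generations. Each generation applies the deterministic genic-selection
   update p′ = p(1−s)/(1−ps) to deleterious/LoF sites before resampling, and
   new mutations enter at the rescaled rate 2Nμ L per generation at
   frequency 1/(2·drift_size). A bottleneck substitutes the reduced size for
   the affected epoch of the focal population's terminal branch.
3. **Sampling.** Sample allele counts are hypergeometric draws from the pool
   when no drift phase exists (making θ̂π and θ̂w exactly unbiased for θ in
   the single-population neutral case) and binomial otherwise.
4. **Haplotype placement (LD).** Within each population the derived alleles
   of each site are placed on the 2n haplotypes by a copying-rank process: a
   per-haplotype rank variable is redrawn along the chromosome with
   probability 1 − e^(−4Neρ·d) over distance d, and each site's k derived
   copies go to the top-k ranks. Marginal counts are untouched (every
   k-subset is exchangeable), while nearby sites share carriers, giving r²
   that decays with distance at a scale set by ρ; ρ = 0 yields complete
   linkage and a flat r² curve. A bottlenecked population uses its reduced
   size in the rate, so bottlenecks lengthen LD, as in real data. This is a
   deliberately lightweight stand-in for a recombination graph: it produces
   the right qualitative decay and ordering between populations but not
   calibrated map distances.
5. **Sweep injection.** Inside the interval center ± `half_width`, each
   focal-population haplotype is independently replaced with probability
   `final_freq` by one template haplotype, so the beneficial haplotype
   reaches the configured frequency in expectation and within-interval
   diversity collapses as final_freq → 1. Missing genotypes stay missing.

All randomness flows from one `numpy` generator seeded with the single
config seed, so outputs are bit-reproducible. The generator writes VCF v4.2
(GT:DP), a reference FASTA consistent with the REF column, GFF3 gene models
(regular single-exon CDS, strands alternating), a per-site annotation TSV
(effect label, SIFT score, gene and Pfam ids), a population map and a
ground-truth JSON.

### What the simulations do not show

Sites are exchangeable given the copying process: there is no recombination
map, no gene conversion, no linked selection outside injected sweeps, and no
realistic demography for any particular species. SIFT scores are drawn
uniformly in [0, 0.05) for deleterious/LoF and [0.05, 1] otherwise so the
classification threshold partitions classes exactly — real SIFT scores
straddle the boundary. Passing tests therefore demonstrate that the
estimators and the scan recover what the model puts in, not that any real
cohort satisfies the model.

### Key defaults

| parameter | default | rationale |
|---|---|---|
| Ne | 10,000 | typical long-term size for outcrossing trees |
| μ | 2.5×10⁻⁹ /bp/gen | standard plant nuclear rate |
| ρ | 1×10⁻⁸ /bp/gen | gives LD half-decay of a few kb at Ne = 10⁴ |
| split_times | (7000, 3000) | inter- then intra-group divergence, F_ST ≈ 0.3 / 0.15 |
| bottleneck | (pop 1, 3000 gen, ×0.2) | a bottlenecked derived population |
| class fractions | 0.40/0.30/0.25/0.05 | synonymous/tolerant/deleterious/LoF within CDS |
| s (deleterious) | 2.5×10⁻⁴ | 2Ne·s = 5, weak purifying selection |
| missing rate | 0.02 | never applied to the outgroup |
| pool_size / drift_size | 400 / 200 | spectrum resolution / drift rescaling |

No published selection coefficients exist for the motivating system; s is a
free suppression parameter exposed in the config.

## Filters and site selection

Hard filter: a site is removed iff QUAL < 30 ∨ QD < 2 ∨ MQ < 30 ∨
MQ0/DP > 0.1. The removal criteria are strict inequalities, so boundary
values (QUAL = 30, …) pass. MAF filtering retains sites with minor-allele
frequency strictly above the threshold (default 0.05), computed on
non-missing allele copies. Multiallelic records and indels are dropped at
read time with logged counts.

Four-fold degenerate (4DTv) sites are the third positions of codons whose
first two bases fix the amino acid under the standard code (eight codon
families), strand-aware, with CDS phase applied at the transcript 5′ end.
Where alternative transcripts overlap, a position is 4DTv only if it is
four-fold degenerate in every transcript covering it (conservative
intersection).

Coordinates: VCF/GFF3 are 1-based inclusive on disk; everything internal is
0-based half-open, with the conversion confined to one utility pair.

## Diversity, differentiation, inbreeding

Missing genotypes are excluded site-wise (pairwise-complete); a missing call
removes that sample's two copies from the site's counts. Window denominators
use total window length, not accessible length — the convention implied by
standard windowed-scan tools — and are configurable. Windows tile each
chromosome from position 0; trailing short windows are kept and flagged
`partial`.

Tajima's D uses the window's modal per-site copy number m for the variance
constants and flags windows where m varies by more than 10% (`m_varies`) or
S < 3 (`few_segregating`); S = 0 windows are undefined. F_ST is the
two-population Weir–Cockerham weighted ratio of sums; per-window negatives
are reported as-is in TSV output and clamped to zero only before
Z-standardization, which keeps the Z distribution stable on small cohorts.
The inbreeding coefficient follows the observed/expected-homozygosity form
with the m/(m−1) small-sample correction on expected heterozygosity,
counting sites genotyped in the individual and polymorphic in the cohort.

## LD

r² is the squared Pearson correlation of 0/1/2 dosage vectors
(Rogers–Huff), appropriate for unphased diploids; an EM haplotype-frequency
r² is out of scope. Decay curves bin all intra-chromosomal pairs within
`max_dist` by distance between 1-based positions. The half-decay distance is
the first bin midpoint at or below half the curve's global maximum — with the
caveat that the bin width must resolve the decay scale, otherwise the curve
starts at its background floor and the half point is flagged unreached.

Pruning slides windows of 50 surviving SNPs advancing by 5; an offending
pair (r² ≥ 0.5) loses its lower-MAF member, ties dropping the downstream
site; passes repeat until no removal, which makes pruning a fixed point on
its own output and guarantees no surviving pair within window − step = 45
retained SNPs at or above the threshold. The per-test significance threshold
is 1 / (retained SNP count).

## Burden

Polarization keeps sites where the outgroup is homozygous; outgroup-het and
outgroup-missing sites are excluded and ledgered with reasons. Nonsynonymous
sites split at SIFT < 0.05 (deleterious) vs ≥ 0.05 (tolerant); "high"-effect
sites are LoF regardless of SIFT; nonsynonymous sites without a score are
excluded with a warning. Per-sample derived totals are 2×hom + 1×het per
class and dSNP/sSNP divides derived-allele totals (not site counts). The SFS
drops sites with zero derived copies. Pfam burden averages derived
frequencies of deleterious and synonymous sites per family and ranks by
their ratio; the top cut flags ⌈0.05·n⌉ families, extended through ties at
the boundary; families without synonymous sites are undefined and never
flagged. The cohort heterozygous fraction per class is the mean of
per-sample fractions by default (samples without derived sites in the class
excluded); a pooled-count mode is provided because either aggregation is
defensible.

## Sweep scan

Z-scores standardize each statistic over all finite windows genome-wide
(population sd). Windows with zero focal diversity have an undefined π-ratio,
are excluded from the standardization and can never qualify on that
statistic — which is why the injected "strong sweep" test uses final
frequency 0.95 rather than 1.0.

The μ statistic multiplies three factors over windows of W consecutive SNPs
(default W = 50, sliding one SNP; a fixed-10-kb window mode exists):
μ_var = span·S_total/(W·L) (≈1 under uniform SNP density, large over the
SNP-sparse valley of a sweep); μ_sfs = (ξ₁+ξ_{m−1})/W (singletons plus
near-fixed derived sites — derived counts when outgroup polarization is
available, folded minor counts otherwise, in which case the ξ_{m−1} term is
inert); μ_ld = (mean within-flank r²)/(2·mean cross-flank r² + ε) with
ε = 10⁻⁶ guarding zero cross-flank LD. These normalizations are this
package's contract for the composite diversity/SFS/LD idea; they are chosen
so each factor has a neutral expectation of order one.

Combination: a bp window qualifies on μ if it contains the midpoint of a
top-5% μ window; the default combine mode is "all" (intersection of
Z(π-ratio) > 3, Z(F_ST) > 3, top-5% μ), with "any" and "at-least-k" exposed
because intersection vs union is a genuine design choice. Qualifying
windows merge when overlapping or abutting (0-based half-open, end = start
merges); genes overlap a region by ≥ 1 bp to be reported.

The sweep-recovery experiment simulates two populations split 0.2·2Ne
generations, a 2-Mb chromosome and one sweep of 40-kb half-width at the
center: the footprint is kept small relative to the chromosome so the
genome-wide Z standardization is dominated by neutral background, mirroring
a ~100-kb window scan on a hundreds-of-Mb genome.

## Numerical and edge-case policy

Undefined values (zero-variance r², S = 0 Tajima's D, empty FST windows,
families without synonymous sites) are NaN plus an explicit flag, never
silently zero. Site filters are idempotent. Estimator code paths are checked
against independent straight-line oracles (brute-force pairwise differences,
a second transcription of the Tajima constants, the W&C algebra in its
general r-population form, `corrcoef`) at 10⁻¹² relative tolerance in the
test suite, and the generator is cross-checked against an independent
coalescent simulator where available.

## Problem sizes

Replicate counts and sequence lengths in the tests and the acceptance script
(50 neutral replicates at 1 Mb / n = 20; 15–20 replicates per F_ST split
time; 12–20 sweep replicates at 2 Mb) were chosen as the smallest designs
whose Monte-Carlo error is comfortably below the property margins being
asserted.
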