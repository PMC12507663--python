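# Methods

`xenopop` implements the genomic inference chain that demonstrates obligate
cross-species cloning in an ant host/parasite-like system: a host species
(*"ibericus"* in the package's labels) whose queens cannot produce workers
without sperm from a second, well-diverged species (*"structor"*), and which
maintain a clonal lineage of that species' males inside their own colonies —
males that carry the host's mitochondria. Every stage runs on a bundled
synthetic-colony generator with planted truth, so the whole chain is testable
without any external data.

## The inference chain

**F1 detection from heterozygosity.** A first-generation hybrid between two
species with fixed nucleotide differences is heterozygous at every such
site, so its fraction of heterozygous calls over a polymorphic SNP panel
sits an order of magnitude above conspecific diploids. The panel applies the
standard filters: per-call genotype quality strictly greater than 10 (calls
at the threshold are masked), indels removed, minor allele frequency ≥ 0.05
among called allele copies, and ≥ 80% of individuals called. The
per-individual statistic divides heterozygous calls by the *full* panel
size (not the individual's called sites); a per-called-sites mode exists as
a sensitivity flag. Classification splits the sorted values at the largest
gap and flags the upper cluster only when the ratio of cluster means exceeds
a guard (default 5), so a cohort without real structure flags nobody. A
borderline individual (e.g. het proportion 0.58 between an 0.8 cluster and
an 0.05 cluster) joins the hybrid side of the largest gap.

**Supervised two-source ancestry.** With source allele frequencies taken
from the pure individuals of each species, the admixture fraction q of a
putative hybrid maximizes `sum log(q p_M + (1-q) p_P)` over carried allele
copies. Frequencies are clipped to [1e-3, 1-1e-3] so fixed differences
cannot produce infinite log-likelihoods; the 1-D maximization is bounded on
[0,1] to tolerance 1e-6. An error-free F1 on a fixed-difference panel lands
at exactly 0.5; unsupervised structure inference (latent source
frequencies) is deliberately out of scope.

**Reference-guided phasing.** The maternal species has very low diversity
(πs ≈ 4.5e-4), so one homozygous conspecific reference genome — the
highest-coverage non-hybrid queen — identifies the maternal allele at nearly
every heterozygous site of a hybrid. The rule table, in precedence order:
below 3 reads in either genome → N; missing call → N; reference
heterozygous → N; hybrid heterozygous with one allele matching the
homozygous reference → that allele maternal, the other paternal; no shared
allele → N. A site homozygous in both hybrid and reference is assigned to
both haplomes (both parents necessarily carry the allele); because the
strictly literal rule assigns only at hybrid-heterozygous sites, a `strict`
mode masks these instead. Phased alleles substitute into the maternal
species' reference backbone per gene; unassigned panel sites become N, and
genes with more than 50% N/gaps are dropped. With a truly homozygous
reference and error-free genotypes the paternal haplome has *zero* errors at
assigned sites; when the maternal species is polymorphic, sites where the
hybrid's maternal haplotype differs from the reference queen are
mis-oriented (the maternal-derived allele is read as paternal) — an error
mode inherent to the method, small in proportion to maternal diversity, and
visible in the simulator by setting the maternal πs target above zero.

**Placement.** Species and lineage assignment use p-distances (mismatches
over jointly non-N positions, undefined below 100 overlapping sites) to
reference panels: a query joins the panel with the smallest mean distance,
with support from a site-bootstrap (columns resampled with replacement;
panels collapse identical columns so each replicate is a small
matrix-vector product). Distance ties resolve to "unassigned" rather than
an arbitrary panel. Neighbor-joining trees (negative branch lengths clamped
to zero, the excess moved to the sister branch) are provided for lineage
visualization; likelihood tree inference is out of scope because the chain
consumes only clade membership and support. Mito-nuclear mismatch — the
cloning signal — is flagged when the nuclear genome and the mitochondrial
haplotype place in different species; either side unassigned yields an
indeterminate record, never a flag. Clonal clusters are single-linkage
components at a small distance threshold (default 3x the expected pairwise
distance implied by the clonal πs target); the cluster with the lowest mean
pairwise distance among multi-member clusters is "clonal-like". Eggs are
typed on fixed-difference diagnostic sites: ≥99% paternal-only calls →
androgenetic (paternal_only), ≥90% heterozygous → hybrid, fewer than 20
called diagnostic sites → indeterminate. The 99%/90% thresholds are
pragmatic choices for a qualitative call; they are not estimated from data.

**Diversity and load.** πs and πn follow Nei–Gojobori counting under the
standard code: per codon position, the synonymous site fraction is the share
of single-base changes preserving the amino acid, excluding changes to
stops from the denominator (so syn + nonsyn = 3 for every sense codon);
multi-difference codons average over minimal mutational paths, excluding
paths through stops. Differences and sites pool over all unordered sequence
pairs and genes with equal pair weight. Codons containing N are skipped for
the affected pair, and sequences with >20% N in a gene are dropped for that
gene. Confidence intervals are a percentile bootstrap over genes (the
resampling unit for genome-wide per-lineage panels); a πs of 0 reports an
undefined (NaN) ratio, never infinity. The πn/πs ratio indexes genetic
load: the clonal lineage, with its tiny effective population size, shows
collapsed πs and roughly doubled πn/πs relative to the wild-type lineage.

## The synthetic-colony generator

The generator models site patterns directly instead of running a coalescent:
the analyses consume only genotype patterns, and direct placement keeps
every expectation closed-form.

* **Genome.** 200 genes x 150 codons (90 kb) of random sense codons per
  gene; one contig per gene; all coordinates 1-based.
* **Species divergence.** Interspecific fixed differences placed per site
  with probability 0.01 (stop-creating changes rejected), giving ~900
  diagnostic sites — enough to saturate F1 heterozygosity and pin ancestry,
  playing the role the genome-wide SNP panel plays on real data. The "over
  5 Myr" divergence of the real pair enters only through this knob.
* **Clonal lineage.** The clonal pool is a private branch off the wild-type
  base (default 1e-3 per site) plus polymorphism at its own low πs target.
  Its divergence from the wild pool is an order of magnitude below the
  interspecific density: a distinct clade, same species.
* **Polymorphism calibration.** Within-lineage variants are placed only at
  positions where the change is synonymous (respectively nonsynonymous) for
  the lineage base, with derived-allele frequencies drawn from a neutral-ish
  1/i spectrum on a 20-chromosome grid. Candidate sites are accepted until
  the realized sum of 2f(1-f) meets the class budget (target π x NG sites),
  with a fractional final acceptance — the expectation matches the target
  and the generative variance is minimal, which is what makes
  recovery-of-target tests meaningful at 90 kb scale. Defaults: πs 4.5e-4
  (host), 1.4e-3 (wild paternal), 2.7e-4 (clonal); πn/πs 0.21 (host and
  wild), 0.43 (clonal).
* **Individuals.** The default composition mirrors the study's sampling:
  164 F1 workers (144 clonal-sired, 20 wild-sired), 127 non-hybrid controls
  (50 host queens, 24 host males, 53 wild paternal-species males), 24
  clonal males carrying host mitochondria, 8 eggs (6 biparental, 2
  androgenetic) and one spermatheca holding one host plus one clonal sperm
  genome. Haploid males are emitted as homozygous diploid VCF calls and
  flagged by ploidy in the metadata. Depth is Poisson(30) per call and
  genotype quality a clipped rounded Normal(60, 15); genotypes derive from
  the true haplotypes with no error unless a symmetric allele-flip
  probability is switched on.
* **Mitochondria.** One haplotype per species (2 kb, 2% interspecific
  divergence) plus small per-individual variation (5e-4); clonal males and
  all F1s carry the host haplotype.
* **Pool draws.** Individuals draw haplotypes independently
  (Bernoulli per site at the site's frequency). `draw_pool(...,
  exact_frequencies=True)` instead gives each site the carrier count whose
  sample pairwise diversity best matches 2f(1-f) — the right mode for
  calibration checks, where binomial sampling noise would otherwise dominate.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linked variation and recombination within genes,
demographic history, selection beyond the fixed syn/nonsyn mix,
mapping/calling artifacts and allelic dropout, indels (the indel filter is
exercised on hand-built fixtures only), multi-species outgroups, and any
correlation between depth, quality and genotype error. Error-free
simulation makes the zero-confusion acceptance checks a test of the
*inference logic*, not of robustness to noisy sequencing.

## Numerical and design choices

* MAF uses called allele copies only; multi-allelic sites keep the
  second-most-frequent allele as "minor". "max-missing 0.8" means ≥ 80% of
  individuals called.
* The phasing stage runs on the quality-masked, indel-free panel *without*
  MAF/missingness filters: those filters would discard exactly the
  low-frequency within-lineage variants that distinguish clonal from
  wild-type fathers. The heterozygosity panel applies the full filter set.
* Problem sizes: the shipped scenario (90 kb, 324 individuals) runs the
  whole chain in ~2 minutes on one core; gene count and length scale the
  panel linearly.
* The rank-sum comparison uses the exact null for tie-free samples of ≤ 25
  per group (the normal approximation is orders of magnitude off in the
  tails), asymptotic otherwise.
* Bootstrap support resamples alignment columns, not individuals.
* Determinism: every stochastic step takes a seed or Generator;
  fixed seeds give byte-identical VCFs and reports.

## Known limitations

* The F1 classifier is a 1-D gap rule with a separation guard — adequate
  when hybrids and non-hybrids are well separated (the regime here), not a
  general mixture model, and it cannot detect backcrosses.
* Ancestry estimation is supervised; it requires pure-source panels and
  inherits any contamination in them.
* Placement is distance-based; with very short sequences or heavy masking
  the margins shrink and queries fall back to "unassigned".
* The clonal-cluster threshold derives from the clonal πs target; on real
  data it would need calibrating against the observed distance distribution.
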