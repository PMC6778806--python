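# Methods

## Model and design

The package measures paralog sequence collapse (PSC) through the contrast of
observed heterozygosity between haploid and diploid tissue genotypes called
against the same reference transcriptome. The core identity is that a
haploid genotype has one allele: a heterozygous call from haploid reads can
only arise from reads of two distinct loci co-mapping (or from error). All
statistics are per callable bp so that references of very different sizes
are comparable.

The simulated study design mirrors a conifer seed family: `n_mothers = 6`
unrelated maternal genotypes, each contributing

* **ME** — one haploid megagametophyte sample (one maternal haplotype; a
  single whole-genome haplotype index per individual, i.e. no recombination),
* **EM** — one diploid embryo: the megagametophyte haplotype plus a paternal
  haplotype drawn uniformly from the population pool (unknown pollen donors,
  panmixia),
* **VEG** — one pooled diploid vegetative sample carrying the maternal
  genotype.

Per gene, the 12 maternal haplotypes are drawn **without replacement** from
the pool of `n_pool_haplotypes = 40`. Unrelated mothers justify distinct
lineages, and the choice makes the pooled unbiased pi of the VEG group an
exactly unbiased estimator of the pool's all-pairs diversity; drawing with
replacement would introduce a (n-1)/n ~ 2.5% downward bias.

## Population simulation and theta calibration

Each gene gets a random ancestral sequence (`gene_length = 1500` bp) and a
pool of n = 40 haplotypes. Sites segregate independently with probability
`p_seg`; a segregating site receives a derived-allele count i drawn from the
neutral SFS, P(i) proportional to 1/i (i = 1..n-1), carriers chosen uniformly,
derived base uniform among the three alternatives. Since the expected
pairwise difference per segregating site under this SFS is 1/a with
a = sum_{i<n} 1/i, setting `p_seg = theta * a` makes the pool's expected
all-pairs Hamming diversity per bp equal theta. The default
`theta = 4.2e-3/bp` is the study's assumed total-site diversity for the
species. theta large enough to push p_seg above 1 is rejected at config
validation.

Paralog families are two-member: for a fraction `paralog_fraction` of genes
(paired consecutively), the partner's ancestor is a copy of the first
member's ancestor mutated at per-bp probability `paralog_divergence`, after
which the partner gets its own polymorphism. Realized divergence is recorded
per family. Only SNP variation exists anywhere — no indels, so all
haplotypes of a family are positionally homologous, which the mapping
emulation exploits.

Expression weights are log-normal (`expression_logmean = 0`,
`expression_logsd = 0.5`, normalized to mean 1 — a moderate realistic spread;
calibration experiments set logsd = 0 where depth heterogeneity is not under
study). Isoforms, when enabled, are interval truncations of the gene with a
Dirichlet split of the gene's expression; the default is one full-length
isoform per gene, which is sufficient for every heterozygosity result (the
isoform machinery exists to exercise the SuperTranscript path).

## Reference-building strategies

* **redundant** — one contig per distinct expressed allele/isoform sequence
  (exact duplicates merged, provenance records all sources).
* **clustered** — CD-HIT-style greedy clustering of the redundant set,
  longest first (ties by contig id): a member joins the first representative
  with identity >= `cluster_identity = 0.95`; the representative sequence is
  retained. Identity is matching positions over the offset-zero overlap
  divided by the shorter length; since alleles and paralogs are equal-length
  and positionally homologous this is Hamming identity. Comparisons are
  restricted to contigs of the same paralog family — unrelated simulated
  genes are i.i.d. random sequences at ~75% divergence, so no identity
  cutoff of interest could ever join them; the restriction only saves time.
  A clustered contig whose provenance spans >= 2 genes is truth-collapsed
  (PSC-positive) by construction.
* **supertranscript** — per gene: isoforms failing the pre-filter
  (length <= 300 bp or total effective count <= 10) are dropped with a
  keep-longest fallback; survivors are merged block-wise. An incoming
  isoform block is absorbed when it matches already-placed bases at >=
  `block_merge_identity = 0.95` over the overlap, otherwise it is appended
  after the primary sequence — which is how mosaic contigs (consecutive
  near-duplicate blocks) arise from divergent alleles. The threshold is the
  package's own choice (the upstream SuperTranscript tool publishes no such
  parameter) and is exposed in `SimConfig`.

## Mapping emulation

Reads are not simulated individually. Mapping is decided per `read_len =
150` bp window of each expressed haplotype copy, with window starts every
`map_window_step = 30` bp: real reads start at every offset, and coarse
150-bp tiling grossly underestimates the chance that some read placement
near a divergent site clears the mismatch cap. A window maps to a placement
(a contig region positionally homologous to the window, deduplicated to
distinct loci) iff its mismatch fraction is <= `map_max_mismatch_frac =
0.025`; with `map_unique_only` the best placement must be unique — ties are
discarded, emulating a unique-locus mapping rule. Each mapped window
contributes Poisson(`mean_depth` x expression share x step/read_len) reads,
so expected interior coverage equals the expression-scaled mean depth
(coverage ramps at contig edges, as in real pileups). Sequencing errors
substitute each read base with probability `error_rate` to a uniformly
random other base.

Two consequences worth stating because they are *results* of the rules, not
artifacts: (1) reads from a paralog more than ~2.5% divergent rarely map, so
the haploid-het signal of collapsed contigs peaks below the cap and falls at
high divergence; (2) under the redundant strategy, windows identical across
allele contigs multimap and are discarded while discriminating windows reach
only carrier samples, so redundant references lose nearly all callable
coverage — the extreme of diversity underestimation through read splitting.

## Genotype caller

All groups, including haploid ME, are called in **diploid mode**: haploid
heterozygosity is the measurement target and would be unobservable under
ploidy-1 calling. At a sample site, an allele is retained iff count >= 2 and
frequency >= 0.2 (package defaults, exposed in `CallerParams`); one retained
allele is homozygous, two heterozygous, more flags the site multi-allelic.
Quality is the Phred-scaled likelihood ratio between the called genotype and
the best alternative under a symmetric error model with the caller's assumed
`error_rate = 0.01` (floored at 1e-6 so the likelihood stays proper for
error-free simulations).

## Site filters and callable accounting

Per contig and ploidy group: a sample's call is void when depth < 10; a site
is dropped when its missing fraction (missing + voided) exceeds 0.5;
polymorphic sites are kept only as biallelic SNPs with site QUAL > 20. The
caller produces no site-level QUAL, so the package defines it as the best
genotype quality among carriers of the minor allele (the samples evidencing
the polymorphism); minor-allele count ties break toward the smaller base
code. Surviving monomorphic and polymorphic sites are both callable.

Two denominators are tracked deliberately: `n_sites` (distinct callable
positions — the "callable sites" of the report tables and of the >100-site
reporting cutoff) and `n_obs` (surviving per-sample site-observations). H_o
is micro-averaged over `n_obs`; per-site pi uses pooled called alleles
across the group's non-missing samples, `pi = (n^2 - sum c_k^2)/(n (n-1))`
computed as one integer-ratio division (hence exactly equal to the all-pairs
difference fraction), averaged over `n_sites`. Under Hardy-Weinberg both
estimators have expectation 2p(1-p) per site, so aggregate H_o/H_E tends to
1 — with one denominator the ratio would be off by the sample count.
Ratios with zero or undefined denominators are reported as NA, never 0.

## Screening rules

* multi-copy: trimmed (10 bp per edge) query intervals of hits with identity
  strictly > 85; any doubly-covered query position makes the transcript
  multi-copy. Otherwise >= 50% trimmed coverage of the transcript length
  (any identity) makes it single-copy; else unassigned. The 50% requirement
  applies only to single-copy assignment — multi-copy needs only overlapping
  hits.
* mosaic: any self-hit whose query and subject intervals differ (the
  full-length identity match and other diagonal self-matches are not
  evidence); invariant to query/subject swap and hit order.
* organelle: any hit with e <= 5e-2 and identity >= 80 (inclusive).
* contaminant: any hit with e <= 1e-5 and identity >= 65 (inclusive).
* low expression: gene-level mean TPM <= 10 (strict > retains).

Real BLAST searches are consumed as outfmt-6 tabular files. For synthetic
references the package's own seed-and-extend aligner (exact 11-mer seeds,
diagonal run joining, X-drop ungapped extension, affine-penalty chaining of
collinear segments, rough Karlin-Altschul e-values; forward strand only,
matching the indel-free simulator) produces the hit tables; tests verify it
against optimal Smith-Waterman alignments. Its self-hit thresholds default
to >= 60 bp and >= 80% identity, the package's own choice for mosaic
detection.

## Numerical choices and degenerate inputs

* Reproducibility: every stage draws from an independent substream derived
  by hashing (master seed, stage label); identical configs give identical
  outputs, and stages can be re-run in isolation.
* N50 uses the descending-cumulative convention; ExN50 pools expression
  across samples and takes the smallest descending-expression prefix whose
  share reaches x%.
* VCF I/O is 1-based (pysam) against the 0-based internal convention;
  monomorphic records carry a `<NON_REF>` placeholder ALT; indel records on
  input are skipped and counted; per-sample qualities round-trip through a
  float `QS` FORMAT field.
* Zero-length supertranscripts cannot occur (keep-longest fallback);
  zero-callable transcripts yield `None` statistics, excluded from
  aggregation rather than counted as 0.

## Problem sizes

Calibration experiments use 300-500 genes x 1500 bp (~0.5-0.75 Mbp, about
4M callable site-observations), 100,000 sites x 50 diploids for the HWE
check, and 6 paralog pairs per divergence point for the dose-response —
sizes chosen so Monte-Carlo error is well inside each check's tolerance
while a full run stays in the minutes range on one core.

## What the simulator does and does not emulate

Emulated: family-structured ploidy contrast, neutral-SFS polymorphism
calibrated to theta, two-member paralog families, assembly redundancy and
collapse, unique-best mismatch-capped mapping, depth/error noise, the filter
chain, and all screening rules. Not emulated: indels/SVs and MNPs, splice
graphs (isoforms are interval truncations), reverse-strand and chimeric
reads, mapping-quality modeling, allele-specific expression, linked
selection or LD (sites segregate independently), assembler internals, and
real contaminant/organelle databases (those screens run on supplied tabular
hits). Passing tests therefore validate the statistical chain and the rule
implementations under these idealizations — they do not certify behavior on
real libraries, where fragmentation, expression bias and alignment artifacts
add noise the generator does not model.

## Known limitations

* The identity used by the clustering emulation is offset-zero Hamming-style
  identity; internal-block isoforms of a gene are not clustered with their
  full-length parent (real CD-HIT would align them). With the default single
  isoform per gene this has no effect.
* Detection power for collapse falls sharply once paralog divergence exceeds
  the mapping mismatch cap; this is faithful to the mapping rules but means
  highly divergent collapse is invisible to the haploid diagnostic.
* The dose-response oracle treats sites in different 150-bp blocks as
  independent; shared window depths correlate nearby sites, which the test
  handles with a block-conservative variance bound.
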