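# Methods

## Problem setting

Samples are cultures of a clonally farmed red seaweed. Most were purified
through a single haploid cell, so their conchocelis-phase genomes are
expected to be homozygous diploid at every locus; one sample is a sister
species, and one is an interspecific F1 whose conchocelis genome carries
both full parental chromosome sets (allotetraploid, AABB) but is genotyped
by a diploid-coded caller. Inputs are a merged multi-sample VCF (GT and GQ
per call) and a sample-metadata table; all analyses operate on a
samples × biallelic-SNV matrix of genotype classes.

## Filtering model

Three filters run in a fixed order, each with full site/call accounting:

1. **GQ mask** (default `min_gq = 20`): calls with known GQ below the
   threshold become missing. The order is fixed because masking feeds the
   next filter.
2. **Site missingness** (default `max_missing = 0.1`): sites whose
   missing-call fraction exceeds the threshold are dropped.
3. **Heterozygous-site removal**: any site heterozygous in any
   homozygous-expected sample is dropped genome-wide. A doubled haploid
   cannot be truly heterozygous, so residual HET calls indicate collapsed
   repeats, paralogy or contaminant mismapping rather than genotype.

Multiallelic and non-SNV records are dropped (not split) at read time and
counted: the downstream statistics are site-based and assume two alleles;
dropping is conservative and logged. Phased separators are accepted as
unphased; half-calls are missing.

## Allotetraploid trio test

Informative loci are those where parent A is HOM_REF and parent B HOM_ALT
(both called). The hybrid's genotype at each informative locus falls into
two-ref / het / two-alt / unclassified (missing); the four counts always
partition the informative set. The verdict statistic is the heterozygous
fraction of *classified* loci (missing excluded — the natural denominator,
since unclassified loci carry no evidence either way). The default
threshold 0.8 separates a genuine allotetraploid (observed fractions near
0.9–1.0) from contamination-style scenarios; with fewer than
`min_classified = 100` classified loci the verdict is "insufficient data"
rather than a guess. Only the (A = HOM_REF, B = HOM_ALT) orientation is
used by default; the mirrored orientation is available as an option.
Conditioning on parental fixed differences also suppresses loci mismapped
from contaminating bacterial reads, which rarely satisfy the two-parent
condition. No region mask is applied by default; passing the nuclear-rRNA
mask separates the homogenised repeat region (expected 100% parent-B
class) from the rest of the genome (expected 100% het).

## IBS distances and classical MDS

Per-site similarity between two samples is dosage agreement,
`1 − |d_i − d_j|/2` with ALT dose `d ∈ {0,1,2}`; the distance is one minus
the mean similarity over sites called in both samples. Missingness is
handled pairwise rather than by listwise site deletion so realistic
missing data does not erase the matrix; a pair sharing no called site is
an error, not a silent zero. The ordination is Torgerson scaling:
double-centre the squared distances, eigendecompose, take coordinates
from the top-k nonnegative eigenpairs. Negative eigenvalues (IBS
distances need not be Euclidean) are truncated to zero and their mass
reported; no additive correction is applied. Coordinates are determined
only up to rotation/reflection/translation, so tests compare
reconstructed distances, never raw axes. The hybrid-midpoint statistic
projects the hybrid onto the segment between its parents in ordination
space: `t = (H−A)·(B−A)/|B−A|²`, with an off-axis component normalised by
|B−A|. For an allotetraploid the diploid-coded dose is exactly the
parental mean at every locus, so `t ≈ 0.5`; in practice the surrounding
cluster structure shifts it slightly (≈0.55 on simulated defaults).

## Group-specific screen

A locus is a candidate for a case group iff all called cases share one
genotype class, that class occurs in zero called controls, and the
missing-call counts in each group are within tolerances (defaults 0). A
locus with every case missing is never a candidate. The candidate set is
monotone non-decreasing in both tolerances. The published screens of this
kind finish with manual genome-browser inspection; this implementation
instead exports per-locus evidence (class and missingness counts) and
leaves judgement to the analyst, so candidate counts are not expected to
match a manually curated list.

## Organelle comparison

Variable sites of a genotype matrix are exported as a FASTA alignment
(HOM_REF → reference base, HOM_ALT → alternate base, HET and missing →
N). HET is exported as N rather than an IUPAC code because the
phylogenetic sample sets are homozygous by design and downstream tools
treat N uniformly. Parsimony-informative columns are those with at least
two called states each present in at least two sequences.

The mitochondrial:chloroplast rate comparison uses mean pairwise
distances over the sample pairs shared by the two alignments — identical
pair sets by construction, so the ratio of means is a clean rate
contrast. Distances are raw mismatch fractions over co-called columns
(p-distance) or Jukes–Cantor corrected (`d = −¾ ln(1 − 4p/3)`). The JC69
option is the matched estimator for the simulator (which evolves
sequences under Jukes–Cantor) and is what the reproduction script uses;
p-distance is the assumption-free default. With a zero chloroplast mean
and positive mitochondrial mean the ratio is reported infinite with a
warning rather than raising.

## Synthetic study design

The simulator generates truth genomes and an observed VCF with the
statistical structure the analyses assume. Defaults are the desk-scale
study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_chrom × chrom_length` | 2 × 50 kb | nuclear genome size |
| `n_clusters` | 3 | focal-species clusters |
| `fst` | 0.2 | Balding–Nichols cluster differentiation |
| `n_samples_per_cluster` | 7 | doubled haploids per cluster |
| `n_admixed` | 2 | samples drawing from two clusters' frequencies |
| `species_divergence` | 0.01/site | sister-species substitution probability |
| `strain_subgroups` | 2 | subgroups within the first cluster ("strain") |
| `shared_mutations_per_subgroup` | 20 | exclusive planted flips per subgroup |
| `private_mutations_per_sample` | 5 | per-member private flips |
| `rrna_mask` | chr1:10001–12000 | nuclear-rRNA homogenised region |
| `organelle_length` | 20 kb | cp and mt alignment length |
| `cp_rate` | 0.01 subst/site | chloroplast root-to-tip depth |
| `mt_cp_ratio` | 10 | mitochondrial:chloroplast rate contrast |
| `error_rate`, `missing_rate` | 0.002, 0.02 | per-call noise |

Within-species polymorphism: a fraction `min_polymorphic_fraction`
(default 0.02) of sites get an ancestral frequency ~U(0.05, 0.95) and
per-cluster frequencies from the Balding–Nichols Beta
(`p(1−F)/F, (1−p)(1−F)/F`); haploid alleles are Bernoulli draws and every
non-hybrid diploid genotype is the doubled haplotype, hence homozygous
everywhere. The sister species substitutes each site independently with
probability `species_divergence`. The first sample of the first cluster
and the sister sample are the hybrid's two source haplotypes; the
hybrid's genotype is their unordered pair except inside the rRNA mask,
where it is the doubled second-parent allele (post-hybridisation repeat
homogenisation). Subgroup mutations are planted at distinct monomorphic
sites (configs requesting more than are available are rejected); the
first subgroup is labelled "abnormal" to exercise the screen.

Organelles: one Yule genealogy over all non-hybrid samples (dendropy,
seeded), branch lengths scaled so the root-to-tip depth equals `cp_rate`
substitutions/site; cp and mt sequences evolve under Jukes–Cantor on the
same tree, the mt branch lengths multiplied by `mt_cp_ratio` — both
organelles are uniparentally co-inherited, so one genealogy serves both.
The hybrid's cp and mt sequences are copies of the donor parent's
(default: the sister species).

Observation: with probability `error_rate` a call is replaced by a
uniformly chosen *different* genotype class (so an error on a homozygous
call lands on HET with probability 1/2); with probability `missing_rate`
it becomes missing. GQ is drawn uniformly from 30–99 for faithful calls
and 2–40 for erroneous ones, making the GQ < 20 filter meaningfully
selective (it removes 18/39 of erroneous calls and no correct ones). The
error profile of real joint-called data is unknown; these defaults are
placeholders surfaced in the config. One master seed determines every
output; stage streams are derived with fixed offsets.

What the simulator does **not** emulate: read-level artifacts (mapping
bias, bacterial contamination tracks), indels and structural variants,
linkage disequilibrium within clusters (sites are independent given the
frequencies), chloroplast heteroplasmy, and realistic GQ–error
correlation beyond the two uniform ranges. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to every real-data pathology.

## Numerical and design notes

- Positions are 1-based inclusive throughout; BED files are 0-based
  half-open and converted on read.
- Genotype class codes equal ALT dose (0/1/2, −1 missing), so dosage
  arithmetic is direct.
- The verdict threshold comparison is `≥` (a fraction exactly at
  threshold passes).
- MDS uses `numpy.linalg.eigh` on the symmetrised centred matrix;
  eigenvalues at or below zero contribute zero coordinates.
- The reproduction script simulates 10 samples × 10 kb organelles and
  averages the JC69-estimated ratio over 10 derived seeds; at these sizes
  the estimator's spread is a few percent, comfortably inside the ±20%
  recovery band the tests assert.
- Problem sizes in the test suite (2 × 50 kb genomes, ≤ 25 samples,
  20-seed replicate loops) were chosen so the whole suite runs in well
  under a minute while keeping every statistical check adequately
  powered.

## Known limitations

- The group screen reproduces the pre-inspection candidate logic only;
  manually curated candidate counts from real studies are not
  recoverable.
- The rate-ratio estimator is a pairwise-distance surrogate for
  tree-based rate comparison; with deep divergence and p-distance it
  saturates (JC69 mitigates this).
- `read_multisample_vcf` reports malformed records with record
  coordinates, not raw line numbers (htslib does not expose them).
- IBS/MDS makes no LD pruning or sample reweighting; highly related
  samples will dominate axes exactly as they do in the field's standard
  tools under default settings.
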