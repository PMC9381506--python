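# Methods

## Scope and data model

`phoscycle` measures the *potential* of a marine microbial community to
cycle phosphonates, from gene-family reference databases and tabular
translated-search results. Fourteen phosphonate gene families are tracked
(five biosynthesis, six substrate-specific catabolism, three C-P lyase
subunits) plus five conserved single-copy markers used as a community-size
proxy. The package does not build alignments or trees, run the translated
search itself, or perform read QC — it consumes an aligned FASTA, per-
sequence metadata, and m8 hit tables, which are the stable interfaces of
those external tools.

## Database curation

**Residue verification.** Functional membership of a family is decided by
conserved residues (catalytic, substrate-binding, cofactor-binding).
Rules are data, not code: each rule names an anchor sequence present in
the alignment, a 1-based position on the *ungapped* anchor, and an allowed
residue set. Positions are mapped through the anchor's gap structure to
alignment columns; a sequence is kept iff it satisfies every rule. A gap
at a rule column counts as failure — the residue is absent. Anchor
sequences always pass their own rules, so a rule file can never eliminate
its own frame of reference. The repository ships synthetic example rule
files; real rule sets are supplied by the user in the same TSV format.

**Synteny rescue.** *phpC* and *phnY* cannot be identified reliably by
annotation alone (they sit inside large alcohol-dehydrogenase and
aldehyde-oxidoreductase superfamilies), so candidate sequences
additionally require another phosphonate-cycling gene on the same contig
within a locus-rank window. The window defaults to 10 ranks — "close
proximity" is not a published number; 10 ranks comfortably covers an
operon while excluding unlinked loci — and is configurable. Candidates
absent from the locus table are unverifiable and excluded.

**Dereplication.** Non-redundant (nr) databases are built by greedy
clustering at 99 % identity, mirroring the conventions of greedy
incremental clusterers: sequences are processed longest-first (ties broken
lexicographically by id); each joins the first existing cluster whose
*representative* it matches at ≥ threshold, else founds a new cluster.
Identity is the number of identical aligned residues divided by the length
of the shorter sequence. The match count is defined as the maximum over
all global alignments (a longest-common-subsequence recurrence): this
makes identity a deterministic function of the sequence pair, with no
dependence on which co-optimal traceback an aligner happens to report.
The nr database keeps the representatives; each cluster's full member and
genome list is retained for reporting.

**Normalization factors.** Per family, the copy-number factor is
genomes/sequences of the nr database and the length factor is the
study-wide mean sequence length divided by the family's mean length. The
study mean is computed over the union of the 14 phosphonate databases
only — the markers have their own internal normalization (below), and
mixing them into the phosphonate mean would couple the two scales.
Genome counts are taken over the retained records (representatives for an
nr database), which keeps both factors in (0, 1]; counting the union of
cluster-member genomes instead can exceed the sequence count whenever a
cluster spans genomes and would push the factor above 1. Sequence lengths
are used as found in the input FASTA (post-trimming, if the user trimmed).

## Screening and counting

Hits are standard 12-column tabular rows. Per read, only the best hit is
kept (max bitscore, ties by min e-value, then input order). A hit counts
iff its percent identity meets the family threshold — 50 % for *pepM,
aepY, phnA, phnW, phnX, phnZ, phnI*; 55 % for *phnM*; 60 % for *phpC,
mpnS, hepD, palA, phnJ*; 65 % for *phnY* — over at least 32 aligned amino
acids for 100 bp reads or 40 for 125 bp reads. All thresholds are
inclusive. Forward and reverse mates are distinct reads and both count;
because each family is screened against its own database, a read may
legitimately count toward more than one family. Marker genes pass through
the same machinery with a 50 % identity default.

## Abundance

normalized count = raw × copy-number factor × length factor. Community
size is the mean of the five marker counts, each scaled by
length(recA)/length(marker) so longer housekeeping genes do not inflate
the denominator; marker "length" is the mean reference length of the
marker's database and is a configurable input (defaults: recA 350, atpD
460, tufA 395, gyrB 640, hsp70 640 aa). Relative abundance is
100 × normalized/community-size. Samples with zero community size are
excluded and listed, never imputed; values above 100 % are reported with
a warning (they can arise legitimately from multi-copy families or
normalization scale). Rates per 100 000 reads are provided for
transcript-style reporting.

Note one deliberate property of this normalization: phosphonate counts are
length-referenced to the *study mean* length while the community size is
referenced to *recA*. The ratio of the two (≈ 1.02 under the default
synthetic lengths) is a constant scale shared by all families, so
between-family and between-sample comparisons are unaffected.

## Statistics

* **Co-occurrence** — from the redundant databases' genome × gene presence
  matrix: cell(src, co) = |genomes with both| / |genomes with src|;
  asymmetric by construction; source genes with zero genomes yield an
  undefined (NaN) column, reported.
* **Diversity** — Shannon H = −Σ p ln p over class labels, Pielou
  J = H/ln S (undefined at S = 1). Natural log throughout; the choice of
  base rescales H and cancels in J.
* **ANOVA / Tukey HSD** — standard between/within decomposition;
  Tukey-Kramer q for unbalanced pairs with adjusted p from the
  studentized-range distribution (scipy's numerically integrated CDF).
* **Phosphate regression** — OLS of ln(relative abundance) on
  ln(Pi + 0.01); the 0.01 µmol/L pseudocount keeps below-detection samples
  in the model. Samples with missing phosphate or zero abundance are
  excluded and counted (only the Pi axis has a published pseudocount, so
  zero abundances are not imputed). Natural logs; slope significance is
  base-invariant, the slope scale is not.
* **Bray-Curtis / ANOSIM** — d = Σ|x−y|/Σ(x+y); ANOSIM
  R = (mean between-group rank − mean within-group rank)/(M/4) over all
  M pairwise distances with mid-ranks for ties, p by the add-one
  permutation estimator with a mandatory seed; an exhaustive mode
  enumerates all label permutations for small n. NMDS ordination is
  deliberately not implemented — the distance matrix is exported for any
  standard ordination tool.

Printed-evenness caveat: published class tallies for *pepM* (H = 2.66,
S = 70) imply J = H/ln S ≈ 0.63, yet 0.59 is sometimes quoted; the package
defines and documents Pielou J and asserts nothing about externally
printed evenness values.

## Synthetic data: what it emulates and what it does not

The generator plants every quantity the pipeline is supposed to recover.

* **Communities** — n = 200 genomes by default; classes drawn from a
  Dirichlet-weighted pool of 10 marine-typical classes; log-normal
  relative abundances (σ = 1, a typical rank-abundance spread); per-gene
  Bernoulli carriage with survey-like prevalences (common: *phnW* 0.25,
  *pepM* 0.15, *phnZ* 0.15; rare: *hepD* 0.01, C-P lyase genes ~0.04) and
  a conditional override P(*aepY* | *pepM*) = 0.86 reflecting the tight
  linkage of the first two biosynthesis steps; constant integer copy
  numbers (default 1).
* **Hit tables** — per sample, gene, and genome, passing-read counts are
  Poisson with rate total_reads × abundance × copies × length / 10⁵.
  This is the minimal model under which the copy-number and length
  factors are *exactly* the right inverse transforms, so recovery tests
  have an analytic expectation; it is a statement about what the
  corrections assume, not about real sequencers. True-hit identities are
  uniform on [threshold, 100]; decoys are planted strictly below either
  the identity cut-off or the alignment-length cut-off, so filter
  correctness is testable exactly. Default depth: 10⁶ reads per sample
  (recovery tests use 20 seeds at this depth; smaller studies in the
  pipeline tests use 2–5 × 10⁵ to stay fast).
* **Reference databases** — substitution-only evolution from a random
  ancestor: cluster founders diverge 30 % from each other, members sit at
  99.5 % identity to their founder (safely above the 99 % threshold, with
  cross-cluster identities far below it), conserved residues are planted
  to satisfy the shipped rules with a configurable violator fraction, and
  locus tables isolate a configurable fraction of synteny candidates.
  Because evolution is substitution-only, the emitted "alignment" is the
  sequences themselves; gapped-alignment handling is exercised separately
  with explicit gapped fixtures.

Not emulated: read-level sequence content (no FASTQ), sequencing error,
chimeras, compositional correlations between taxa and gene content, and
cross-family homology (decoys are below-threshold by construction rather
than borderline homologs). Passing tests therefore demonstrate the
pipeline's arithmetic and filtering are exact under the stated model, not
that the thresholds themselves are optimal for real data — threshold
choice is inherited from the survey design.

One global seed drives a hierarchical seed tree (per sample, per gene),
so any subset of the outputs reruns reproducibly and full reruns are
byte-identical.

## Numerical choices and degenerate inputs

Inclusive (≥) thresholds everywhere. Best-hit ties resolved
bitscore → e-value → input order. Empty rule lists are refused unless an
explicit pass-through flag is set (verifying with no criteria is a silent
no-op otherwise). Empty databases: dereplication warns and returns empty;
factor computation raises, naming the gene. ANOVA refuses single groups,
groups of one, and zero total variance. ANOSIM refuses groups with fewer
than two members and requires an explicit seed; exhaustive enumeration is
capped at n ≤ 9. Tukey p-values are clamped to [0, 1]. The regression
requires ≥ 3 usable points. Relative abundances are reported at full
precision in memory; file outputs round to 6 significant digits.

## Acceptance measurements

`scripts/acceptance.py` recomputes, from scratch at run time: end-to-end
abundance recovery (20 seeds × 10⁶ reads; worst gene-level
|mean error|/3 SE), length-bias ratios before/after normalization (two
families with identical carrier sets, lengths 300 vs 900 aa), copy-number
recovery (two-copy family), filter exactness over all 14 thresholds × both
read-length profiles, dereplication agreement with a brute-force greedy
oracle at 50 sequences, exhaustive-permutation ANOSIM agreement at n = 6,
ANOVA/Tukey closed-form agreements, co-occurrence exhaustive-count
agreement, ANOSIM null rejection rate (500 simulations, 8+8 samples — a
configuration whose 12 870 distinct groupings make the permutation null
effectively continuous, where the add-one estimator is exactly
calibrated), planted regression-slope recovery (100 replicates), and the
ANOSIM R of depth-structured communities. The same functions back the
acceptance test suite, so asserted and reported numbers come from one
code path.

## Known limitations

* The survey's published ocean-scale abundance figures depend on the
  TARA/MOTS raw metagenomes and the published genome-level supplementary
  dataset; the package reproduces the *measurement procedure* and
  validates it on synthetic truth, and recomputes the database-derived
  printed values only when the user supplies that dataset
  (`data/supplementary_dataset_s1.tsv`).
* Greedy dereplication is quadratic in the worst case and intended for
  family-sized databases (10²–10⁴ sequences), not whole-proteome scales.
* The identity definition (max matches over global alignments / shorter
  length) is deliberately tool-independent; it can differ in the third
  decimal from a specific aligner's banded identity for distant pairs,
  which is immaterial at a 0.99 threshold.
* Marker lengths default to typical bacterial values; surveys with
  unusual marker composition should supply measured database means.
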