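# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `viropipe`. All coordinates are 0-based
half-open; all sequences are canonicalized to uppercase with U→T on
input.

## Synthetic communities

The generator emulates the statistical structure of peat-soil viromes so
that every downstream stage has ground truth:

- **Genome classes.** Linear dsDNA phage genomes drawn uniformly on
  10,001–25,000 nt with viral-category annotation 1 or 2 (probability
  0.6/0.4; an optional `p_category3` fraction gets tier 3 for testing
  "sensitive" selection). Circular Microviridae genomes on 4,000–8,000 nt
  and circular CRESS genomes on 1,000–5,000 nt, each carrying one marker
  ORF; their viral category is `none`, reflecting that small ssDNA
  genomes are typically missed by automatic viral classifiers.
  Contaminants are packaged PhiX/M13-like references (synthetic
  stand-ins, see `data/contaminants.synthetic.fasta`) mutated at 0.2–2%
  nucleotide divergence.
- **Marker ORFs.** The packaged seed alignments
  (`viral_rep_like.synthetic.afa`, 110 aa; `phage_f_like.synthetic.afa`,
  420 aa) are synthetic stand-ins for the Rep and capsid-F domain
  families: a random background-composition consensus plus four variants
  at 5% divergence. Real domain alignments in aligned FASTA are accepted
  through the same interface. Each simulated genome embeds its marker as
  the consensus mutated at 2–10% amino-acid divergence (initiator M
  preserved), reverse-translated with uniformly random synonymous codons,
  preceded by an in-frame stop so the ORF caller reports the marker from
  its own ATG.
- **Abundances.** Lognormal(0, σ) within class (σ = 1 by default),
  normalized, then the ssDNA classes are jointly rescaled so their
  *length-weighted* share — the expected read fraction — equals the
  target (default 4%, the share observed in soil viromes where both
  virus types co-occur). Group structure for multi-sample runs: each
  group draws a base profile at σ, samples jitter it at σ = 0.35, so
  samples cluster by group the way replicate cores cluster by core.
- **Reads.** Inward-facing pairs, insert 300 ± 30 nt, default 2×100 nt,
  uniform fragment starts (wrapping the origin on circular genomes),
  i.i.d. substitution errors at 1% per base. Pair count is
  `n_read_pairs / coverage_depletion_factor` (rounded). Treatment
  effects: `coverage_depletion_factor` ≥ 1 emulates particle-purification
  loss; `ssdna_dropout` zeroes ssDNA sampling weights (bead-beating);
  `extraction_dropout_rate` randomly zeroes genomes (kit bias).
- **Contigs.** Each genome is emitted as one contig; circular genomes are
  linearized with a 30 nt direct terminal repeat so circularity is
  re-detectable. An optional fragmentation knob splits named genomes into
  ≥ 2 linear pieces for robustness tests.

What the simulator does *not* model: indel sequencing errors, quality
profiles, PCR-amplification coverage unevenness (observed in real
amplified viromes but not quantified in a usable form), GC bias, chimeric
assembly. Passing tests therefore demonstrate the correctness of the
pipeline's logic under substitution-only noise and complete assemblies,
not robustness to assembly artifacts.

## Circularity and ORFs

Circularity is an exact direct terminal repeat ≥ `min_repeat` (default
20 nt; repeat capped at half the contig, contigs shorter than
2·min_repeat are rejected); the redundant 3′ copy is trimmed. DTR
detection is the assembly-signature convention for circular genomes; at
20 nt the chance of a spurious repeat in a random 25 kb contig is
~25000·4⁻²⁰ ≈ 2×10⁻⁸.

The ORF caller is deterministic and dependency-free: six-frame
translation, stop-to-stop segments (sequence ends count as open
segments), reported from the first ATG, minimum 30 aa. Circular contigs
are scanned doubled so origin-spanning ORFs are found once; ORF length is
capped at length/3 aa.

## ANI / aligned fraction and dereplication

The production aligner finds exact shared 15-mers, groups them by
diagonal, extends each diagonal gaplessly with an X-drop criterion
(match +1, mismatch −3, drop 30), and greedily chains blocks that overlap
< 20% on the query. ANI = matches / aligned columns over all blocks; AF =
query positions covered by blocks / query length, with the *shorter*
sequence as query, which makes the result symmetric under argument swap.
Indels between homologous blocks surface as distinct diagonals; within a
block the model is substitution-only, matching the simulator. The
strand with the higher ANI·AF product is reported. An exhaustive
affine-gap Smith-Waterman (`ani_exhaustive`; match +2, mismatch −3, gap
open 5, extend 2) serves as the independent reference on small instances
and agrees with the chained engine on planted-divergence constructs.

Dereplication is greedy: contigs sorted by length descending (ties by
id) either join the first representative they match at ≥ 95 ANI / ≥ 85 AF
or seed a new vOTU — the sort makes the outcome input-order invariant,
and membership is tested against representatives only, as in standard
dereplication practice. The > 10 kb dsDNA rule is applied to
representatives *after* clustering, so a 9 kb fragment can still be
absorbed by a > 10 kb population. Contaminant screening reuses the same
engine with thresholds > 95 ANI / ≥ 80 AF and the AF denominator on the
*screened contig* ("across 80% of the contig" read as the query contig;
the alternative contaminant-relative reading would only matter for
contigs much longer than the contaminant).

## Marker profiles and the two-step ssDNA search

The marker model is a gapped position-specific scoring matrix, not a full
profile HMM: per-column scores are half-bit log-odds
2·log₂(p/bg) with p the background-blended column frequency
(p = (f + 0.5·bg)/1.5 — frequency-based, so duplicating input sequences
leaves the profile unchanged) and bg the Robinson-Robinson amino-acid
frequencies. Columns with > 50% gaps are dropped. Profiles built from
unaligned proteins use a star alignment to the longest member (ties by
id), global with free end gaps, BLOSUM62, gap open/extend −11/−1;
insertions relative to the center are discarded.

Search is local profile-to-sequence alignment with affine gaps (open 10,
extend 1, half-bit units). Significance comes from explicit calibration:
1,000 background-composition decoys are scored and fitted to a Gumbel by
maximum likelihood; E = N·sf(score) under the fitted null with N the
number of searched proteins. The nominal cutoffs (score ≥ 50 half-bits,
E ≤ 0.001) match the values commonly used with hmmsearch, but the score
scale is **not** HMMER's — the calibrated E-value is the operative
filter, and the decoy false-positive rate at the defaults is ≤ 0.005 by
construction (verified over 2,000 shuffled decoys in the tests).

The two-step procedure: (1) search seed profiles against proteins of
circular contigs only — presumed complete ssDNA genomes; (2) build one
new profile per marker from the step-1 hit proteins and search it
against all proteins, recovering diverged or linearized relatives. Calls
are classified by the circularity/size windows (Microviridae: circular,
4–8 kb, capsid hit; CRESS: circular, 1–5 kb, Rep hit; otherwise
flagged-only). A contig hit by both marker types is reported in a
separate conflicts list rather than silently classified.

## Read recruitment and abundances

Mates are mapped independently (no proper-pair constraint): exact 13-mer
seeds every 6 positions on both strands propose placements over the
concatenated representatives; each candidate is scored gaplessly over the
full read, the best placement wins (ties: representative id, then
leftmost coordinate, forward strand first), and a read is retained iff
identity ≥ 90% over its full length. A banded edit-distance refinement
(band ±5) rescues placements whose gapless identity falls in [70, 90),
counting indel columns as mismatches. Under the simulator's
substitution-only errors the gapless path is exact; at the default cutoff
the acceptance of a read is decided by its realized substitution count
(binomial), though — as with any seeded mapper — k-mer seeding loses
sensitivity as divergence approaches the identity cutoff. Reads spanning
the origin of a circular genome do not map end-to-end to the linearized
representative and are dropped; for the shortest CRESS genomes this loses
~5–10% of their reads and biases the recruited ssDNA share slightly
below the simulated target (well within a percentage point at default
settings).

Abundance A = (mapped bases / representative length) · (10⁹ / total
sample bases), i.e. mean depth per Gbp of metagenome; covered fraction
C_f = percent of positions with depth ≥ 1 (breadth at depth ≥ 1, the
usual reading of a "fraction of the contig covered" detection rule).
A is zeroed where C_f < threshold (default 10%; sweeps over 0–75% are
built in and detection counts are non-increasing in the threshold by
construction). The log₁₀ display view masks zeros rather than adding a
pseudocount — zeros mean "not detected", not "rare".

## Community statistics

Shannon H uses the natural log (the convention of the standard ecology
packages); J = H/ln R is reported missing for R ≤ 1. Bray-Curtis for two
all-zero samples is defined as 0 with a warning. PCoA is classical
scaling: double-center −½D², eigendecompose, order by eigenvalue, report
coordinates on positive-eigenvalue axes and the full spectrum including
negative eigenvalues.

Sample clustering reproduces the pvclust-style procedure: the feature
matrix is, by default, the Bray-Curtis matrix itself with samples as
columns, and the between-sample distance is the Euclidean distance
between its columns, under complete linkage. This double transform
(Euclidean over a dissimilarity matrix) is statistically unusual but is
retained as the default for comparability with common practice;
`feature_matrix="abundance"` clusters the abundance table directly.
Multiscale bootstrap: for each scale r ∈ {0.5, …, 1.4}, 1,000 replicates
resample round(r·n_features) feature rows with replacement; each
reference node's per-scale proportion BP_r is clipped to
[1/(B+1), B/(B+1)] and fitted by weighted least squares (binomial
weights) to Φ⁻¹(1−BP_r) = v√r + c/√r, giving AU = 1−Φ(v−c) and
BP = 1−Φ(v+c). A node at the ceiling (present in every replicate at
every scale) is reported AU = BP = 100 directly — the probit fit of a
clipped constant is degenerate and would understate saturated support;
symmetrically an all-zero node reports 0. The scale-1 proportion agrees
with a direct bootstrap within Monte-Carlo error (checked against a
10,000-replicate oracle in the tests).

## Determinism and problem sizes

Every stochastic stage takes an explicit seed or Generator; a pipeline
run with a fixed config reproduces all artifacts byte-identically. The
shipped test-suite and acceptance-script problem sizes — a 45-genome
default community at 2×10⁵ read pairs, 60-contig oracle comparisons at
2 kb, 2,000 decoys, 50 screening communities, 1,000 bootstrap replicates
per scale (10,000 for the direct oracle) — were chosen so a full
verification completes in a few minutes on one CPU while keeping
Monte-Carlo error well below the assertion tolerances.

## Known limitations

- The profile model is a PSSM with affine gaps, not Plan7; scores are
  not comparable to HMMER bit scores (by design, documented above).
- The recruitment aligner is seeded and substitution-oriented; highly
  indel-rich reads or divergence at the identity cutoff reduce
  sensitivity.
- Assembly, read QC and viral-category classification are consumed as
  inputs (the simulator supplies ground-truth categories); the pipeline
  neither assembles nor classifies viral vs microbial contigs.
- Dereplication clusters the pooled contig set and records per-member
  provenance; it does not cluster per habitat.
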