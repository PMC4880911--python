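# Methods

## Model and procedure

`mut3d` asks, per gene and cancer type, whether somatic missense
mutations are more spatially concentrated on the protein's tertiary
structure than uniform placement would produce. The chain of steps:

1. **Mutation cleaning.** MAF-style rows are deduplicated on
   (sample, chromosome, position, alt allele) — the alt allele is part of
   the key so two genuinely different substitutions at one site both
   survive. Candidate germline variants are removed by exact
   (chrom, pos, alt) match against a user-supplied blacklist; two styles
   are distinguished, a 1000 Genomes common-SNV style list (`filter1`,
   the default) and a validated-dbSNP style list (`filter2`). The
   conservative `filter2` style is known to delete genuine cancer
   hotspots, which is why `filter1` is the default. Missense SNVs with a
   parseable protein position are retained; the codon index comes from
   the MAF's own annotation (re-annotation from genomic coordinates is
   out of scope).
2. **Structure reduction.** Each chain residue is represented by its
   C-alpha coordinate, falling back to the centroid of heavy atoms when
   C-alpha is absent; residues with no atoms carry no coordinate and are
   excluded from distance computation and null sampling. Only the first
   model of multi-model entries is read; alternate locations resolve by
   highest occupancy (ties: first seen); waters and non-amino-acid
   HETATM records are ignored, but amino-acid HETATMs such as
   selenomethionine stay in the chain (MSE → M); other nonstandard
   residues become `X` and are barred from the sampling universe. These
   conventions are fixed choices for reproducibility, not properties of
   the PDB format.
3. **Mapping.** The chain sequence is globally aligned to the reference
   protein (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 1;
   deterministic tie-breaking by the aligner's first optimum). Pairwise
   alignment is sufficient because only two sequences are ever compared;
   for the dominant case — a chain that is a near-exact fragment of the
   reference — any sensible aligner returns the same correspondence.
   QC requires gap_count/alignment_length < 0.5 (strict) and aligned
   chain residues / chain length ≥ 0.5 (inclusive). The coverage
   denominator is the structure chain length; the choice of denominator
   is configurable because either convention is defensible. Mutations
   transfer through aligned columns; codons landing in gaps or on
   coordinate-less residues are dropped from the 3D statistic (n counts
   only structure-covered mutations). All in-range codons feed the 1D
   test regardless of structural coverage.
4. **Test.** Observed statistic: mean pairwise Euclidean distance over
   all unordered mutation pairs, multiplicity preserved (hotspots give
   zero-distance pairs). Null: n positions drawn uniformly **with
   replacement** from the residues with coordinates. The estimator is
   p = (k+1)/(m+1) with ties counted in k. Two stages: m = 10⁴ for every
   gene, m = 10⁶ (fresh stream) for genes with stage-1 p ≤ 0.01
   (inclusive). Genes need ≥ 3 structure-mapped mutations to be tested;
   with several structures the lowest p (ties: larger n, then smaller
   structure id) represents the gene. BH q-values are computed within a
   cancer type over exactly the tested genes; significance requires
   q ≤ 0.1 (inclusive) and mutated-sample frequency strictly above 3%.
5. **1D control.** Identical construction on the primary sequence:
   distance |codon_i − codon_j|, universe codons 1..CDS length, using
   all in-range missense mutations.

## Key parameter choices

| parameter | default | rationale |
|---|---|---|
| min mutations on structure | 3 | smallest n for which clustering is meaningfully testable; configurable upward |
| stage-1 / stage-2 draws | 10⁴ / 10⁶ | stage 1 resolves p down to ~10⁻⁴; stage 2 only where it matters |
| escalation threshold | p ≤ 0.01 | an order of magnitude above the significance region, so no borderline gene is left at low resolution |
| q threshold | 0.1 | conventional FDR operating point for candidate generation |
| sample-frequency threshold | > 3% | guards against recurrent artifacts and ultra-rare calls |
| alignment gates | gaps < 0.5, coverage ≥ 0.5 | rejects wrong-isoform and fragmentary matches |
| gap penalties | open 10, extend 1 | standard affine setting for BLOSUM62 |

**Replacement.** Sampling the null with replacement matches the observed
statistic, which counts recurrent codons with multiplicity: the null of
n independent uniform hits can also produce coincident positions. A
without-replacement mode exists (`replacement=False`) for sensitivity
analysis; it cannot reproduce hotspot ties and is therefore
anti-conservative for recurrently mutated genes.

**Randomness.** Every (cancer type, gene, structure, dimension, stage)
combination derives its own stream seed by hashing those tokens with the
base seed (SHA-256 → 64-bit integer). Results are consequently
independent of scheduling order and safe to parallelize; identical
configurations are byte-identical across runs.

## Numerical choices and degenerate inputs

- Tie handling: simulated ≤ observed uses exact float comparison. Exact
  ties arise only when a draw reproduces the observed point multiset, and
  both sides are computed by the same code path on the same coordinates,
  so rigid motion and scaling cannot flip a tie. The exact-enumeration
  oracle adds a 1e-9 relative slack instead, because its summation order
  differs from the observed statistic's.
- A structure whose residues all share one coordinate yields p = 1 for
  any observed set (every simulated distance ties the observed 0).
- n < 2 is undefined and raises; a sampling universe below 2 positions
  raises; p-values outside (0, 1] are rejected by the BH step.
- Length adjustment of average distances (cohort statistics) uses OLS
  residuals of distance on CDS length by default; with a constant-length
  cohort the fit degenerates to the intercept and residuals are centered
  distances. A `ratio` mode (distance / length^(1/3), the isometric
  scaling of a linear dimension with chain volume) is the documented
  alternative, since no single adjustment is canonical.
- Fisher enrichment reports the cross-product odds ratio (inf when a
  margin is empty); Wilcoxon comparisons use exact enumeration for
  tie-free samples with min size ≤ 8, else the tie-corrected normal
  approximation without continuity correction.

## What the synthetic generator emulates — and what it does not

The generator produces every input the pipeline reads: C-alpha-trace PDB
files (ideal helices with canonical 1.5 Å rise / 100° twist / 2.3 Å
radius, 3.8 Å-bond self-avoiding random coils, integer lattices, and
helix hairpins whose arms put sequence-distant residues in spatial
contact), reference FASTA records in which each chain is an exact
substring flanked by 10 extra residues, MAF tables with per-gene planted
models (uniform null; k codons inside a sphere of given radius;
single-codon hotspots), planted germline contaminants mirrored in the
blacklist, duplicate and silent decoy rows, annotation and ground-truth
tables. The standard benchmark is 1,000 genes on 200-residue coils, 10%
drivers with 6-mutation clusters inside a 6 Å sphere, nulls with 6
uniform mutations, 100 samples; each mutation gets its own sample, so
driver genes sit at 6% sample frequency.

Real data differ in ways the generator does not model: non-uniform
mutation rates along genes (the method's null assumes uniformity, which
can flag very large genes spuriously), sequence-dependent mutational
signatures, imperfect structure coverage and crystal-packing artifacts,
isoform ambiguity, and germline contamination beyond exact-match
blacklists. Passing tests therefore demonstrate the statistical
machinery — calibration, power on planted spatial signal, invariances,
threshold semantics — not performance on any real tumor cohort.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their simulations to
single-CPU desk scale: type-I calibration uses 1,000 null genes at
m = 10⁴; power checks use 200 planted-cluster replicates; the end-to-end
benchmark runs the full 1,000-gene cohort at production depths
(10⁴/10⁶). These sizes give binomial standard errors comfortably inside
the asserted bands.

## Known limitations

- Genes without usable structures (or failing alignment QC) are reported
  untestable, not tested — the method's reach is bounded by structure
  availability.
- One chain per structure record; inter-chain (interface) clustering is
  not examined.
- Cohort-scale analyses of real tumor data require external inputs
  (TCGA-style MAFs, a PDB snapshot, gene-to-structure cross-references)
  that this package deliberately does not fetch; all inputs are explicit
  files for reproducibility.
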