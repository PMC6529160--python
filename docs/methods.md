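# Methods

`panmap` re-implements, as a reusable and testable pipeline, the bespoke
computational procedures used to compare two *Arabidopsis thaliana*
accessions at the whole-genome level: read-depth copy-number and
presence/absence calling, pan-genome core/dispensable classification,
TE-gene flagging, reciprocal-best-hit (RBH) synteny comparison with
structural-variant block calling, genetic-linkage anchoring of contigs into
pseudochromosomes, and two genome-distribution statistics. A synthetic-data
module generates every input with planted ground truth so the whole pipeline
runs and is validated offline.

## Per-gene relative coverage and duplication calls (`coverage`)

Reads of both accessions are assumed mapped to one reference assembly
(accession R); `CoverageTrack` holds the resulting per-base depths. The
per-gene statistic is computed in three steps:

1. **Per-gene median depth** over all positions of the gene span, introns
   and zero-depth positions included. The median makes the statistic robust
   to coverage spikes inside the gene.
2. **Accession normalisation**: division by the accession-wide per-position
   *median* depth (the "average" is a median throughout, which removes the
   sequencing-depth scale).
3. **Per-gene median normalisation**: division by the median of the step-2
   values over genes with nonzero value. This second normalisation absorbs
   accession-specific mapability differences (e.g. systematic sequence
   divergence from the reference) and pins the median relative coverage of
   covered genes at exactly 1.

Classification compares the two accessions' relative coverages v_R and v_Q
with hard, strictly-interpreted cutoffs: `v_R < 0.5 * v_Q` calls the gene
duplicated in Q, `v_R > 1.5 * v_Q` duplicated in R, anything else balanced;
`v_Q = 0 < v_R` is a one-sided duplicated-in-R (presence/absence) call and
`v_R = v_Q = 0` is uncallable. Because every step is a ratio of medians the
calls are invariant under any positive rescaling of either depth track;
values exactly on a boundary are balanced.

**Known limitation.** A clean single duplication (2 copies) of a gene that
is single-copy in the reference assembly produces v_Q/v_R = 2 exactly — the
0.5 cutoff boundary — and is therefore *not* reliably callable with strict
inequalities; only noise decides. Multi-copy events (3+ copies, typical of
tandem arrays) and events whose extra copies are present in the assembly
(ratio 2.0 against the 1.5 cutoff) are well separated. The synthetic
defaults reflect this: planted Q-side duplications carry 3 copies, R-side
duplications 2 copies with both in the assembly.

TE-flagged genes are removed from the duplicated sets after classification.

## Pan-genome classification (`pangenome`)

Given a genes x accessions relative-coverage matrix over a re-sequencing
panel, accessions with average depth strictly below 10x are excluded first
(at-threshold accessions are retained). A gene is **dispensable** iff its
relative coverage is strictly below 0.1 in strictly more than
`min_accessions` (default 100) of the remaining accessions; the remaining
genes are **te** when flagged by the TE-overlap analysis, else **core**.
Dispensable takes precedence over the TE flag. `min_accessions` is an
absolute count (matching a panel of ~1,000); a fractional variant
(`min_fraction`) is available for small panels. The classes partition the
gene universe by construction.

## TE annotation and TE-gene flagging (`te_overlap`)

A TE library mapped against the assembly yields redundant hits. Hits
scoring at least 90% (inclusive) of the library element's own top score are
candidates; candidates are accepted greedily in order of descending
bitscore (ties: longer alignment, then lexicographic TE id) and discarded
on any >= 1 bp overlap with an accepted placement, yielding a
non-overlapping annotation. Genes whose span is covered by the placement
union over strictly more than 80% are flagged as putative TE genes.
Overlap is strand-agnostic; "gene space" is the full gene span (an
exon-restricted mode exists as an option).

## RBH synteny and SV blocks (`rbh_synteny`)

Best hits per query are the maximal-bitscore subjects (ties broken by lower
e-value, then lexicographic subject id, with the tie recorded on the pair);
RBHs are mutually-best pairs. Sorting each genome's genes by (chromosome in
sorted id order, start) assigns genome-wide ranks, so collinear genomes put
RBH pairs on a diagonal.

A pair is a **synteny outlier** when (a) its partner rank deviates from the
median partner rank of up to 5 flanking pairs per side by more than 20
ranks, (b) its partner chromosome differs from the flanking majority, or
(c) it sits in a local partner-rank reversal (the partner rank decreases
both into and out of the pair). Rule (c) is this package's addition: a
small inversion of k genes displaces ranks by at most k-1, so a pure
deviation threshold of 20 ranks is blind to inversions with fewer than ~20
genes, while local reversals identify their interior exactly and never fire
on collinear genomes or on the neighbours of a single relocated gene. The
two edge members of an inverted block have only one reversed adjacency and
are intentionally not flagged; block boundaries are therefore accurate to
one gene.

Maximal runs of >= 3 consecutive outliers with monotone partner ranks are
called **SV blocks**: inversions when the partner rank decreases along the
run, translocations otherwise.

## Linkage anchoring (`linkage`)

**Recombination fractions.** For each marker pair the F2 intercross
likelihood treats the nine two-marker genotype classes as products of two
independent gamete transmissions with recombination fraction r; the double
heterozygote mixes the parental and recombinant phases with weights
(1-r)^2 and r^2. The likelihood is maximised by EM on the expected number
of recombinant gametes (convergence |dr| < 1e-6, <= 200 iterations),
maximised over r in [0, 1] and folded into [0, 0.5] — folding makes the
estimate exactly invariant under an allele-label swap at either marker
(repulsion phase) and is a no-op for correctly phased data. Plants missing
either call are excluded pairwise; a monomorphic marker yields r = 0 with a
degenerate flag. Alongside the ML estimate the estimator reports the
phase-unambiguous counting statistics (recombinant gametes and recombinant
plants among the non-double-heterozygote classes), covering both counting
conventions of per-plant recombination events.

**Grouping, ordering, orientation.** Contigs are clustered by single
linkage with inter-contig distance = minimum pairwise r-hat, joined below
`r_max = 0.25`; degenerate pairs carry no linkage. Within a group the
contig order minimises the sum of adjacent inter-contig minimum r-hat
(exhaustive for <= 8 contigs, greedy nearest-neighbour extension beyond);
of the two mirror-image orders the one whose first contig id is
lexicographically smaller is returned, so results are deterministic and
recovery is assessed up to whole-group mirror. A contig's orientation is
read off the trend of its markers' genetic distance to the neighbouring
contig along the physical marker order; contigs with fewer than two markers
get orientation `?`.

**Pseudochromosomes.** Placed contigs are concatenated with N-gaps
(default 100 bp, written as AGP `U` components), minus-oriented contigs
reverse-complemented. An optional per-group polarity input mirrors whole
groups to match an external chromosome convention. The AGP is exact: the
pseudochromosome FASTA is byte-identically reconstructable from AGP plus
contig sequences.

**Rate comparison.** `compare_recombination_rates` is the two-sample
proportion test (Pearson chi-square on the 2x2 table, 1 df) with Yates
continuity correction, the correction term capped at |O - E| as in R's
`chisq.test`, so equal proportions give chi2 = 0, p = 1 exactly. On the
observed counts 1/60 vs 16/108 it reproduces R 4.3.3 `prop.test`:
chi2 = 5.957, p = 0.0147.

## Distribution statistics (`genome_stats`)

**SV clustering.** SVs >= 1 kbp are assigned by start position to fixed
non-overlapping windows (1 Mbp on real-scale genomes; the pipeline scales
the window down so small synthetic genomes keep ~10 windows per sequence);
the association between per-window count and distance to the centromere
midpoint is quantified by Spearman rank correlation (average ranks for
ties, t-approximation p; undefined on constant input, returned as NaN).

**Gap homologs and homotetramers.** Reference assembly gaps are maximal
N-runs >= 10 bp. For each gap the best hits of its two flanking sequences
against the second assembly are accepted when they land on one target
sequence, same strand, in consistent order, enclosing <= 200 kbp (the
`max_span` default operationalises "spanned with high confidence");
minus-strand homologs are reverse-complemented. Homotetramer counting is
overlapping by default — a run of L >= 4 identical bases contributes L - 3,
N never counts — with a run-based alternative (`mode="runs"`); frequencies
are per kbp. Enrichment of gap homologs over length-matched, N-free random
control sequences (rejection-sampled with a fixed seed, excluded intervals
avoided) is tested two-sided with Mann-Whitney U: exact enumeration for
n_a + n_b <= 12 without ties, otherwise the normal approximation with tie
and continuity corrections.

## Synthetic data (`simulate`)

The generators emulate the statistical structure each stage consumes, with
full determinism under a fixed seed and all truth recorded:

- **Genome pair**: a uniform-ACGT assembly (default 2 Mbp, 2 chromosomes,
  1,000 genes) with disjoint planted variant sets — duplications in Q
  (3 copies), duplications in R (2 copies, assembled), deletions in Q, one
  inverted block of 10 consecutive genes, and TE-covered genes (~90% span
  overlap).
- **Depth tracks**: per-position Poisson with rate `mean_depth * k/m * b_g`
  inside gene g (k copies in the accession, m >= 1 in the assembly) and
  `mean_depth` elsewhere; `b_g` is a lognormal per-gene mapability bias
  with median 1 drawn once per accession. The default log-sd is 0.05: the
  between-accession ratio of two such biases then has log-sd ~0.07, putting
  the 1.5x cutoff 5.7 sigma away, the regime in which the published hard
  cutoffs are usable. With substantially larger mapability spread the hard
  cutoffs break down and would need recalibration.
- **Accession panel**: relative coverages with present genes at
  Poisson(depth)/depth noise around 1, absent genes below a 0.05 noise
  floor, dispensable genes absent from a random 40-80% of accessions, and
  a 5% planted fraction of accessions below the 10x inclusion filter.
- **F2 population**: gamete-wise simulation under the Haldane
  (no-interference) model — crossover probability (1 - e^(-2d/100))/2
  between markers d cM apart — with both meioses recorded, genotypes as
  gamete sums, and independent masking at the missing-call rate. The
  default map is 3 linkage groups x 3 contigs x 3 markers (20 cM per
  contig, 5 cM between contigs, random true orientations).
- **Hit tables**: bidirectional gene-level tables consistent with planted
  orthology (inverted block reversed, deletions absent, duplications as
  adjacent extra copies hitting one reference gene with distinct scores);
  TE-library hits at >= 92% of the library top score plus sub-cutoff
  decoys; gap-flank hits placing each flank at its true target position.
- **Enriched sequences**: homotetramer enrichment plants disjoint 4-runs
  (>= 8 bp apart) on top of the uniform baseline of ~L/64 homotetramer
  positions to reach a requested multiple.

What the simulations deliberately do **not** model: read-level artefacts
(base errors, duplicates, mapping ambiguity), GC- or repeat-driven coverage
waves, crossover interference, segregation distortion, assembly errors, or
realistic TE nesting. Passing recovery tests therefore demonstrates the
correctness and calibration of the *procedures* under their stated
assumptions, not their error rates on real sequencing data.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GFF3/AGP/depth
  TSV are converted at the boundary (1-based inclusive). BLAST tabular
  minus-strand subjects keep `sstart > send` as read.
- Medians of even-sized sets are midpoint means (numpy convention).
- EM initialisation r0 = 0.25; estimates below 1e-8 snap to 0. Agreement
  with a grid-search maximiser is ~1e-6 (the convergence tolerance).
- Greedy TE overlap resolution keeps the higher-scoring of two overlapping
  hits (removing both is the documented alternative reading).
- All randomness flows from one root `numpy.random.default_rng(seed)`;
  outputs are byte-identical under a fixed seed.
- Pipeline outputs carry a provenance header (version, config hash, seed);
  FASTA outputs are covered by the run's `manifest.json` instead, since
  comment lines are not valid FASTA.

## Problem sizes used in the validation suite

Recovery and calibration checks run at: 1,000 genes on 2 Mbp at 30x for
duplication calling; 300 accessions x 500 genes at 15x for the pan-genome;
200 replicates of 500 plants per true r in {0.05, 0.1, 0.2} for estimator
calibration; 1,000 plants, 27 markers, 9 contigs for anchoring; 50 random
200-gene tables for RBH; 50 seeds of 10 vs 10 sequences at 20 kbp for the
enrichment power check. These sizes were chosen so every check is sharp
(multiple standard errors of headroom) while the whole suite stays fast.
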