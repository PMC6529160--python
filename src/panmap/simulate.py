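"""Synthetic genomes, coverage tracks, panels, F2 populations and hit tables.

Every generator takes (or derives) a :class:`numpy.random.Generator` and is
byte-deterministic under a fixed seed, so the whole pipeline can be exercised
end-to-end offline.  The generators plant ground truth (duplications,
deletions, an inverted gene block, dispensable genes, contig order and
orientation, marker map positions) and return it alongside the data, so
recovery tests can score precision and recall exactly.

Defaults emulate the study conditions of a two-accession comparison in a
selfing plant: ~30-110x short-read depth with per-gene mapability bias, a
several-hundred-accession re-sequencing coverage panel, and an F2 mapping
population genotyped at a few dozen PCR markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack, GeneModel, Hit, ValidationError
from .linkage import GenotypeMatrix, Marker

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the two-genotype genome simulation.

    R denotes the reference genotype (its assembly is the mapping target),
    Q the second genotype.  Copy numbers: genes duplicated in Q default to 3
    copies (tandem arrays); genes duplicated in R default to 2 copies, both
    present in the assembly.
    """

    seed: int = 0
    genome_size: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 1000
    gene_length: int = 2000
    n_tes: int = 60
    te_length: int = 400
    n_te_genes: int = 20          # genes whose span is >80% TE-covered
    mean_depth: float = 30.0
    # log-sd of the lognormal per-gene mapability bias; at 0.05 the
    # between-accession coverage-ratio spread stays well inside the 0.5/1.5
    # classification cutoffs (see docs/methods.md)
    bias_spread: float = 0.05
    n_dup_in_q: int = 30
    n_dup_in_r: int = 30
    n_deleted_in_q: int = 10
    dup_q_copies: int = 3
    dup_r_copies: int = 2
    inversion_size: int = 10      # consecutive genes in the inverted block

    def validate(self) -> None:
        counts = [self.n_genes, self.n_tes, self.n_te_genes, self.n_dup_in_q,
                  self.n_dup_in_r, self.n_deleted_in_q, self.inversion_size]
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.mean_depth < 0:
            raise ConfigError("mean depth must be >= 0")
        if self.bias_spread < 0:
            raise ConfigError("bias spread must be >= 0")
        planted = (self.n_dup_in_q + self.n_dup_in_r + self.n_deleted_in_q
                   + self.inversion_size + self.n_te_genes)
        if planted > self.n_genes:
            raise ConfigError(
                f"{planted} planted-variant genes exceed {self.n_genes} genes")
        per_chr = max(1, self.n_genes // max(1, self.n_chromosomes))
        spacing = (self.genome_size // max(1, self.n_chromosomes)) // max(1, per_chr)
        if self.n_genes and spacing < self.gene_length + 200:
            raise ConfigError("genome too small for the requested gene count")


@dataclass
class VariantTruth:
    """Planted differences between genotypes R and Q, and map truth."""

    dup_in_q: dict[str, int] = field(default_factory=dict)   # gene -> copies in Q
    dup_in_r: dict[str, int] = field(default_factory=dict)   # gene -> copies in R (= assembly)
    deleted_in_q: list[str] = field(default_factory=list)
    inversion_genes: tuple[str, ...] = ()
    inversion_interval: tuple[str, int, int] | None = None
    te_genes: list[str] = field(default_factory=list)
    dispensable: dict[str, frozenset[str]] = field(default_factory=dict)
    contig_order: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    marker_cm: dict[str, float] = field(default_factory=dict)

    def expected_duplication_class(self, gene_id: str) -> str:
        if gene_id in self.dup_in_q:
            return "duplicated_in_Q"
        if gene_id in self.dup_in_r:
            return "duplicated_in_R"
        return "balanced"


@dataclass
class GenomePair:
    assembly: dict[str, str]
    genes: list[GeneModel]
    te_intervals: list[tuple[str, int, int]]
    truth: VariantTruth
    #: per-gene (copies in genotype, copies in assembly) for depth simulation
    copy_map_r: dict[str, tuple[int, int]] = field(default_factory=dict)
    copy_map_q: dict[str, tuple[int, int]] = field(default_factory=dict)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_genome_pair(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> GenomePair:
    """Simulate a reference assembly with genes/TEs plus planted R/Q truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_chr = max(1, config.n_chromosomes)
    chr_len = config.genome_size // n_chr
    assembly = {f"chr{i + 1}": random_sequence(chr_len, rng) for i in range(n_chr)}

    genes: list[GeneModel] = []
    per_chr = config.n_genes // n_chr
    extra = config.n_genes - per_chr * n_chr
    gi = 0
    for ci in range(n_chr):
        sid = f"chr{ci + 1}"
        n_here = per_chr + (1 if ci < extra else 0)
        if n_here == 0:
            continue
        spacing = chr_len // n_here
        for k in range(n_here):
            start = k * spacing + 100
            end = start + config.gene_length
            third = config.gene_length // 3
            exons = ((start, start + third), (end - third, end))
            genes.append(GeneModel(gene_id=f"g{gi:04d}", seq_id=sid, start=start,
                                   end=end, strand="+" if gi % 2 == 0 else "-",
                                   exons=exons))
            gi += 1

    truth = VariantTruth()
    order = rng.permutation(config.n_genes)
    cursor = 0

    def take(n):
        nonlocal cursor
        sel = order[cursor:cursor + n]
        cursor += n
        return [genes[i].gene_id for i in sorted(sel)]

    # inverted block: consecutive genes on the last chromosome, clear of the
    # randomly drawn variant genes (those are drawn from the remaining pool)
    if config.inversion_size:
        chr_genes = [g for g in genes if g.seq_id == f"chr{n_chr}"]
        if len(chr_genes) < config.inversion_size + 10:
            raise ConfigError("not enough genes on the last chromosome for the inversion")
        offset = len(chr_genes) // 3
        block = chr_genes[offset:offset + config.inversion_size]
        block_ids = {g.gene_id for g in block}
        order = np.array([i for i in order if genes[i].gene_id not in block_ids])
        truth.inversion_genes = tuple(g.gene_id for g in block)
        truth.inversion_interval = (block[0].seq_id, block[0].start, block[-1].end)

    truth.dup_in_q = {g: config.dup_q_copies for g in take(config.n_dup_in_q)}
    truth.dup_in_r = {g: config.dup_r_copies for g in take(config.n_dup_in_r)}
    truth.deleted_in_q = take(config.n_deleted_in_q)
    truth.te_genes = take(config.n_te_genes)

    by_id = {g.gene_id: g for g in genes}
    te_intervals: list[tuple[str, int, int]] = []
    for i, gid in enumerate(truth.te_genes):
        g = by_id[gid]
        pad = max(1, int(g.length * 0.05))   # cover ~90% of the gene span
        te_intervals.append((g.seq_id, g.start + pad, g.end - pad))
    # remaining TEs in intergenic space
    n_free = max(0, config.n_tes - len(te_intervals))
    gene_sorted = sorted(genes, key=lambda g: (g.seq_id, g.start))
    gaps = []
    for a, b in zip(gene_sorted, gene_sorted[1:]):
        if a.seq_id == b.seq_id and b.start - a.end > config.te_length + 20:
            gaps.append((a.seq_id, a.end + 10, b.start - 10))
    if n_free and gaps:
        picks = rng.choice(len(gaps), size=min(n_free, len(gaps)), replace=False)
        for p in sorted(picks):
            sid, lo, hi = gaps[p]
            start = int(rng.integers(lo, hi - config.te_length))
            te_intervals.append((sid, start, start + config.te_length))
    te_intervals.sort()

    copy_r, copy_q = {}, {}
    for g in genes:
        gid = g.gene_id
        if gid in truth.dup_in_r:
            m = truth.dup_in_r[gid]
            copy_r[gid] = (m, m)
            copy_q[gid] = (1, m)
        elif gid in truth.dup_in_q:
            copy_r[gid] = (1, 1)
            copy_q[gid] = (truth.dup_in_q[gid], 1)
        elif gid in truth.deleted_in_q:
            copy_r[gid] = (1, 1)
            copy_q[gid] = (0, 1)
        else:
            copy_r[gid] = (1, 1)
            copy_q[gid] = (1, 1)

    return GenomePair(assembly=assembly, genes=genes, te_intervals=te_intervals,
                      truth=truth, copy_map_r=copy_r, copy_map_q=copy_q)


def simulate_depth_track(seq_lengths: Mapping[str, int],
                         genes: Sequence[GeneModel],
                         copy_map: Mapping[str, tuple[int, int]],
                         mean_depth: float, bias_spread: float,
                         rng: np.random.Generator,
                         accession_id: str = "sim") -> CoverageTrack:
    """Per-position Poisson depth with per-gene copy ratio and mapability bias.

    Inside gene g with copy numbers (k, m) the rate is
    ``mean_depth * k/m * b_g`` where ``b_g`` is a lognormal factor with
    median 1 and log-sd ``bias_spread`` drawn once per accession; elsewhere
    the rate is ``mean_depth``.
    """
    if mean_depth < 0:
        raise ConfigError("mean depth must be >= 0")
    if bias_spread < 0:
        raise ConfigError("bias spread must be >= 0")
    depths = {sid: rng.poisson(mean_depth, size=int(n)).astype(np.int64)
              for sid, n in seq_lengths.items()}
    for g in genes:
        if g.seq_id not in depths:
            raise ValidationError(f"gene {g.gene_id} on unknown sequence {g.seq_id}")
        k, m = copy_map.get(g.gene_id, (1, 1))
        if m < 1:
            raise ConfigError(f"gene {g.gene_id}: assembly copy number must be >= 1")
        bias = float(rng.lognormal(mean=0.0, sigma=bias_spread)) if bias_spread else 1.0
        rate = mean_depth * (k / m) * bias
        depths[g.seq_id][g.start:g.end] = rng.poisson(rate, size=g.length)
    return CoverageTrack(accession_id=accession_id, depths=depths)


# ---------------------------------------------------------------------------
# accession coverage panel
# ---------------------------------------------------------------------------

def simulate_dispensable_truth(gene_ids: Sequence[str],
                               accession_ids: Sequence[str],
                               n_dispensable: int,
                               rng: np.random.Generator,
                               absent_fraction: tuple[float, float] = (0.4, 0.8)
                               ) -> dict[str, frozenset[str]]:
    """Assign each planted dispensable gene a random absent-accession set."""
    if n_dispensable > len(gene_ids):
        raise ConfigError("more dispensable genes than genes")
    picks = rng.choice(len(gene_ids), size=n_dispensable, replace=False)
    truth = {}
    n_acc = len(accession_ids)
    for i in sorted(picks):
        frac = rng.uniform(*absent_fraction)
        k = max(1, int(round(frac * n_acc)))
        absent = rng.choice(n_acc, size=k, replace=False)
        truth[gene_ids[i]] = frozenset(accession_ids[j] for j in absent)
    return truth


def simulate_accession_panel(gene_ids: Sequence[str], n_accessions: int,
                             dispensable_truth: Mapping[str, frozenset[str]],
                             noise_depth: float, rng: np.random.Generator,
                             low_coverage_fraction: float = 0.05):
    """Relative-coverage matrix (genes x accessions) plus per-accession depth.

    Present genes are centred at 1 with Poisson-derived noise at
    ``noise_depth``; absent genes get a noise floor < 0.05.  A
    ``low_coverage_fraction`` of accessions is generated with average depth
    below 10x, to be excluded by the downstream accession filter.  With
    ``noise_depth=0`` the matrix is noise-free (exact 1/0 values).
    Returns ``(matrix, avg_depth)`` as a pandas DataFrame and Series.
    """
    import pandas as pd

    unknown = set(dispensable_truth) - set(gene_ids)
    if unknown:
        raise ValidationError(f"dispensable truth references unknown genes: {sorted(unknown)[:3]}")
    acc_ids = [f"acc{i:04d}" for i in range(n_accessions)]
    n_low = int(round(low_coverage_fraction * n_accessions))
    low = set(rng.choice(n_accessions, size=n_low, replace=False)) if n_low else set()
    avg_depth = np.empty(n_accessions)
    for j in range(n_accessions):
        avg_depth[j] = rng.uniform(2.0, 9.5) if j in low else \
            noise_depth * rng.uniform(0.8, 1.2) if noise_depth else 30.0

    mat = np.empty((len(gene_ids), n_accessions))
    for i, gid in enumerate(gene_ids):
        absent = dispensable_truth.get(gid, frozenset())
        for j, acc in enumerate(acc_ids):
            if acc in absent:
                mat[i, j] = rng.uniform(0.0, 0.045) if noise_depth else 0.0
            elif noise_depth:
                d = avg_depth[j]
                mat[i, j] = rng.poisson(d) / d
            else:
                mat[i, j] = 1.0
    matrix = pd.DataFrame(mat, index=list(gene_ids), columns=acc_ids)
    return matrix, pd.Series(avg_depth, index=acc_ids, name="avg_depth")


# ---------------------------------------------------------------------------
# F2 mapping population
# ---------------------------------------------------------------------------

def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a map distance in cM (no interference)."""
    if d_cm < 0:
        raise ConfigError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass
class F2Truth:
    """Recorded crossover truth per adjacent marker pair, both conventions."""

    recombinant_gametes: dict[tuple[str, str], int] = field(default_factory=dict)
    recombinant_plants: dict[tuple[str, str], int] = field(default_factory=dict)
    n_gametes: int = 0
    n_plants: int = 0


def simulate_f2_population(markers: Sequence[Marker], n_plants: int,
                           missing_rate: float, rng: np.random.Generator
                           ) -> tuple[GenotypeMatrix, F2Truth]:
    """Simulate F2 genotypes gamete-wise under the Haldane model.

    Markers must carry ``linkage_group`` and ``cm``; within each linkage
    group, crossovers between adjacent markers at distance d cM occur per
    gamete with probability (1 - exp(-2d/100))/2.  Calls are masked to
    missing independently at ``missing_rate``.
    """
    if n_plants < 0:
        raise ConfigError("n_plants must be >= 0")
    if not 0 <= missing_rate < 1:
        raise ConfigError("missing_rate must be in [0, 1)")
    for m in markers:
        if m.linkage_group is None or m.cm is None:
            raise ConfigError(f"marker {m.marker_id} lacks linkage_group/cm")

    marker_order = list(markers)
    idx = {m.marker_id: i for i, m in enumerate(marker_order)}
    groups: dict[str, list[Marker]] = {}
    for m in marker_order:
        groups.setdefault(m.linkage_group, []).append(m)

    codes = np.zeros((n_plants, len(marker_order)), dtype=np.int8)
    truth = F2Truth(n_gametes=2 * n_plants, n_plants=n_plants)

    for lg, ms in groups.items():
        ms = sorted(ms, key=lambda m: m.cm)
        cols = [idx[m.marker_id] for m in ms]
        dists = np.diff([m.cm for m in ms])
        if np.any(dists < 0):
            raise ConfigError("negative map distance")
        rs = np.array([haldane_r(d) for d in dists])
        gametes = np.empty((2, n_plants, len(ms)), dtype=np.int8)
        switches = np.empty((2, n_plants, len(rs)), dtype=bool)
        for g in range(2):
            first = rng.random(n_plants) < 0.5
            sw = rng.random((n_plants, len(rs))) < rs[None, :]
            alleles = np.empty((n_plants, len(ms)), dtype=np.int8)
            alleles[:, 0] = first
            if len(rs):
                cum = np.cumsum(sw, axis=1) % 2
                alleles[:, 1:] = (first[:, None] + cum) % 2
            gametes[g] = alleles
            switches[g] = sw
        geno = gametes[0] + gametes[1]
        for k, col in enumerate(cols):
            codes[:, col] = geno[:, k]
        for k in range(len(rs)):
            pair = (ms[k].marker_id, ms[k + 1].marker_id)
            truth.recombinant_gametes[pair] = int(switches[:, :, k].sum())
            truth.recombinant_plants[pair] = int((switches[:, :, k].any(axis=0)).sum())

    if missing_rate and n_plants:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = -1

    plants = [f"plant{i:04d}" for i in range(n_plants)]
    return GenotypeMatrix(plants=plants, markers=marker_order, codes=codes), truth


@dataclass
class MapTruth:
    markers: list[Marker]
    contig_order: dict[str, list[tuple[str, str]]]   # LG -> [(contig, orient)]
    contig_lengths: dict[str, int]


def simulate_marker_map(n_linkage_groups: int = 3, contigs_per_group: int = 3,
                        markers_per_contig: int = 3, contig_span_cm: float = 20.0,
                        contig_gap_cm: float = 5.0, contig_length: int = 500_000,
                        rng: np.random.Generator | None = None) -> MapTruth:
    """A marker map over contigs with random true orientations.

    Markers are evenly spread over each contig both genetically (``cm``)
    and physically; a contig with true orientation '-' carries its markers
    in reversed physical order relative to the genetic order.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    markers: list[Marker] = []
    contig_order: dict[str, list[tuple[str, str]]] = {}
    contig_lengths: dict[str, int] = {}
    mi = 0
    for lg_i in range(n_linkage_groups):
        lg = f"LG{lg_i + 1}"
        contig_order[lg] = []
        cm_cursor = 0.0
        for ci in range(contigs_per_group):
            cid = f"ctg{lg_i + 1}_{ci + 1}"
            orient = "+" if rng.random() < 0.5 else "-"
            contig_order[lg].append((cid, orient))
            contig_lengths[cid] = contig_length
            cms = np.linspace(cm_cursor, cm_cursor + contig_span_cm,
                              markers_per_contig)
            phys = np.linspace(contig_length * 0.1, contig_length * 0.9,
                               markers_per_contig).astype(int)
            if orient == "-":
                phys = phys[::-1]
            for cm, pos in zip(cms, phys):
                markers.append(Marker(marker_id=f"M{mi:03d}", contig_id=cid,
                                      position=int(pos), linkage_group=lg,
                                      cm=float(cm)))
                mi += 1
            cm_cursor += contig_span_cm + contig_gap_cm
    return MapTruth(markers=markers, contig_order=contig_order,
                    contig_lengths=contig_lengths)


# ---------------------------------------------------------------------------
# hit tables consistent with planted orthology
# ---------------------------------------------------------------------------

def _gene_hit(query: str, subject: str, bitscore: float, qlen: int = 1000,
              identity: float = 98.0, evalue: float = 1e-150) -> Hit:
    return Hit(query_id=query, subject_id=subject, percent_identity=identity,
               align_len=qlen, mismatches=int(qlen * (1 - identity / 100)),
               gap_opens=0, query_start=1, query_end=qlen, subject_start=1,
               subject_end=qlen, evalue=evalue, bitscore=bitscore)


@dataclass
class RBHTables:
    hits_rq: list[Hit]                     # R genes queried against Q
    hits_qr: list[Hit]                     # Q genes queried against R
    genes_q: list[GeneModel]
    expected_pairs: set[tuple[str, str]]   # (R gene, Q gene) truth


def make_rbh_hit_tables(genes_r: Sequence[GeneModel], truth: VariantTruth,
                        rng: np.random.Generator,
                        q_gene_spacing: int = 3000,
                        q_gene_length: int = 2000) -> RBHTables:
    """Bidirectional best-hit tables consistent with the planted truth.

    The Q gene order equals the R order with the inverted block reversed,
    deletions dropped and Q duplications inserted as adjacent extra copies
    (which hit the same R gene with distinct scores).
    """
    gene_sorted = sorted(genes_r, key=lambda g: (g.seq_id, g.start))
    inv = set(truth.inversion_genes)
    deleted = set(truth.deleted_in_q)

    # per-chromosome order with the inversion block reversed
    q_entries: list[tuple[str, str]] = []   # (q_gene_id, r_gene_id)
    by_chr: dict[str, list[GeneModel]] = {}
    for g in gene_sorted:
        by_chr.setdefault(g.seq_id, []).append(g)
    for sid in sorted(by_chr):
        row = [g.gene_id for g in by_chr[sid]]
        if inv:
            pos = [i for i, gid in enumerate(row) if gid in inv]
            if pos:
                lo, hi = min(pos), max(pos)
                row[lo:hi + 1] = row[lo:hi + 1][::-1]
        for gid in row:
            if gid in deleted:
                continue
            n_copies = truth.dup_in_q.get(gid, 1)
            for c in range(n_copies):
                q_entries.append((f"q_{gid}" + (f"_c{c}" if c else ""), gid))

    genes_q = []
    for i, (qid, _) in enumerate(q_entries):
        start = i * q_gene_spacing + 100
        genes_q.append(GeneModel(gene_id=qid, seq_id="q_chr1", start=start,
                                 end=start + q_gene_length, strand="+"))

    hits_qr: list[Hit] = []
    hits_rq: list[Hit] = []
    expected: set[tuple[str, str]] = set()
    best_q_for_r: dict[str, tuple[str, float]] = {}
    for qid, rid in q_entries:
        score = float(500 + rng.integers(0, 20))
        if qid.endswith(tuple(f"_c{c}" for c in range(1, 10))):
            score -= 30.0    # extra copies score below the primary copy
        hits_qr.append(_gene_hit(qid, rid, score))
        prev = best_q_for_r.get(rid)
        if prev is None or score > prev[1]:
            best_q_for_r[rid] = (qid, score)
    for rid, (qid, score) in best_q_for_r.items():
        hits_rq.append(_gene_hit(rid, qid, score))
        expected.add((rid, qid))

    return RBHTables(hits_rq=hits_rq, hits_qr=hits_qr, genes_q=genes_q,
                     expected_pairs=expected)


def make_te_hit_table(te_intervals: Sequence[tuple[str, int, int]],
                      rng: np.random.Generator,
                      top_score: float = 800.0
                      ) -> tuple[list[Hit], dict[str, float]]:
    """TE-library-vs-assembly hits plus the library top-score table.

    Each planted interval yields one hit scoring >= 92% of the library top
    score; a decoy hit below the 90% cutoff is added after each placement.
    """
    hits: list[Hit] = []
    top_scores: dict[str, float] = {}
    for i, (sid, start, end) in enumerate(te_intervals):
        te_id = f"TE{i:03d}"
        top_scores[te_id] = top_score
        score = top_score * rng.uniform(0.92, 1.0)
        length = end - start
        hits.append(Hit(query_id=te_id, subject_id=sid, percent_identity=95.0,
                        align_len=length, mismatches=int(length * 0.05),
                        gap_opens=0, query_start=1, query_end=length,
                        subject_start=start + 1, subject_end=end,
                        evalue=1e-100, bitscore=round(score, 1)))
        # decoy below the score cutoff, elsewhere on the same sequence
        decoy_start = max(0, start - 5 * length)
        hits.append(Hit(query_id=te_id, subject_id=sid, percent_identity=70.0,
                        align_len=length, mismatches=int(length * 0.3),
                        gap_opens=2, query_start=1, query_end=length,
                        subject_start=decoy_start + 1, subject_end=decoy_start + length,
                        evalue=1e-5, bitscore=round(top_score * 0.5, 1)))
    return hits, top_scores


@dataclass
class GapScenario:
    reference: dict[str, str]          # sequence with N gaps
    target: dict[str, str]             # assembly spanning the gaps
    flank_hits: list[Hit]
    enclosed_intervals: dict[str, tuple[str, int, int]]   # gap_id -> target span


def simulate_gap_scenario(n_gaps: int = 5, flank: int = 2000,
                          enclosed_len: int = 1500, spacer: int = 1000,
                          rng: np.random.Generator | None = None,
                          enrich_factor: float = 1.0) -> GapScenario:
    """A reference with N gaps and a target assembly that spans them.

    The target contains, for each gap, the left flank + an enclosed segment +
    the right flank; flank hits place each flank at its true location.  With
    ``enrich_factor`` > 1 the enclosed segments are homotetramer-enriched.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ref_parts, tgt_parts, hits = [], [], []
    enclosed: dict[str, tuple[str, int, int]] = {}
    tgt_pos = 0
    for i in range(n_gaps):
        gap_id = f"gap{i}"
        left = random_sequence(flank, rng)
        right = random_sequence(flank, rng)
        seg = random_sequence(enclosed_len, rng)
        if enrich_factor > 1.0:
            seg = enrich_homotetramers(seg, enrich_factor, rng)
        ref_parts += [random_sequence(spacer, rng), left, "N" * 100, right]
        tgt_parts += [random_sequence(spacer, rng), left, seg, right]
        tgt_pos += spacer
        for side, fseq in (("left", left), ("right", right)):
            qid = f"{gap_id}_{side}"
            hits.append(Hit(query_id=qid, subject_id="tig1",
                            percent_identity=99.0, align_len=flank,
                            mismatches=0, gap_opens=0, query_start=1,
                            query_end=flank, subject_start=tgt_pos + 1,
                            subject_end=tgt_pos + flank, evalue=0.0,
                            bitscore=2 * flank))
            tgt_pos += flank if side == "right" else flank + enclosed_len
        enclosed[gap_id] = ("tig1",
                            tgt_pos - flank - enclosed_len,
                            tgt_pos - flank)
    ref_parts.append(random_sequence(spacer, rng))
    tgt_parts.append(random_sequence(spacer, rng))
    return GapScenario(reference={"ref1": "".join(ref_parts)},
                       target={"tig1": "".join(tgt_parts)},
                       flank_hits=hits, enclosed_intervals=enclosed)


def simulate_clustered_svs(seq_lengths: Mapping[str, int],
                           centromeres: Mapping[str, int], n_svs: int,
                           rng: np.random.Generator,
                           decay_scale: float = 2_000_000.0,
                           min_len: int = 1000, max_len: int = 50_000):
    """SV intervals whose density decays with distance from the centromere.

    Positions are drawn by rejection with acceptance probability
    ``exp(-distance / decay_scale)``, emulating pericentromeric clustering
    of large structural variants.  Returns a list of
    ``(seq_id, start, end, type)`` tuples.
    """
    from .genome_stats import SVRecord

    seq_ids = sorted(seq_lengths)
    lens = np.array([seq_lengths[s] for s in seq_ids], dtype=float)
    weights = lens / lens.sum()
    svs = []
    while len(svs) < n_svs:
        sid = seq_ids[int(rng.choice(len(seq_ids), p=weights))]
        start = int(rng.integers(0, seq_lengths[sid]))
        dist = abs(start - centromeres[sid])
        if rng.random() > np.exp(-dist / decay_scale):
            continue
        length = int(rng.integers(min_len, max_len))
        end = min(start + length, seq_lengths[sid])
        if end - start < min_len:
            continue
        svs.append(SVRecord(seq_id=sid, start=start, end=end, sv_type="sim"))
    return svs


def enrich_homotetramers(sequence: str, factor: float,
                         rng: np.random.Generator) -> str:
    """Plant extra homotetramer runs to reach ~``factor`` x the uniform rate.

    A uniform ACGT sequence has ~L/64 homotetramer positions; (factor-1) *
    L/64 disjoint 4-runs are planted at sites spaced >= 8 bp apart.
    """
    if factor < 1.0:
        raise ConfigError("enrichment factor must be >= 1")
    seq = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    n_extra = int((factor - 1.0) * len(seq) / 64.0)
    sites = np.arange(0, len(seq) - 4, 8)
    if n_extra > len(sites):
        raise ConfigError("sequence too short for requested enrichment")
    picks = rng.choice(len(sites), size=n_extra, replace=False)
    for p in sites[np.sort(picks)]:
        seq[p + 1:p + 4] = seq[p]
    return seq.tobytes().decode("ascii")
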