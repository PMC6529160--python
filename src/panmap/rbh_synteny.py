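"""Reciprocal best hits, rank-based synteny outliers and SV-block calls.

Orthologs between two annotated genomes are proxied by reciprocal best
BLAST hits (RBHs).  Sorting genes of each genome by (chromosome, position)
assigns genome-wide ranks; on collinear genomes RBH pairs then fall on a
diagonal, and pairs whose partner rank deviates from the median of their
flanking pairs are outliers.  Runs of at least three consecutive outliers
with collinear (monotone) partner ranks are called as structural-variant
blocks: inversions when the partner ranks run backwards, translocations
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, Hit, ValidationError


@dataclass(frozen=True)
class RBHPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    tied_best: bool = False     # the best hit was a tie broken deterministically


@dataclass(frozen=True)
class SyntenyBlockCall:
    pairs: tuple[RBHPair, ...]
    sv_type: str                # inversion | translocation

    @property
    def n_genes(self) -> int:
        return len(self.pairs)

    def span_a(self) -> tuple[int, int]:
        return self.pairs[0].rank_a, self.pairs[-1].rank_a

    def span_b(self) -> tuple[int, int]:
        ranks = [p.rank_b for p in self.pairs]
        return min(ranks), max(ranks)


def best_hits(hits: Sequence[Hit]) -> dict[str, str]:
    """Best subject per query: max bitscore, ties by lower evalue then id."""
    return best_hits_with_ties(hits)[0]


def best_hits_with_ties(hits: Sequence[Hit]) -> tuple[dict[str, str], set[str]]:
    """Like :func:`best_hits` but also report queries whose best was tied."""
    best: dict[str, Hit] = {}
    tied: set[str] = set()
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        if h.bitscore == cur.bitscore and h.subject_id != cur.subject_id:
            tied.add(h.query_id)
        if (-h.bitscore, h.evalue, h.subject_id) < (-cur.bitscore, cur.evalue,
                                                    cur.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}, tied


def gene_ranks(genes: Sequence[GeneModel]) -> dict[str, tuple[int, str]]:
    """Genome-wide gene rank by (chromosome order, start); 0-based.

    Chromosomes are concatenated in sorted-id order.
    """
    ordered = sorted(genes, key=lambda g: (g.seq_id, g.start, g.gene_id))
    return {g.gene_id: (i, g.seq_id) for i, g in enumerate(ordered)}


def reciprocal_best_hits(map_ab: Mapping[str, str], map_ba: Mapping[str, str],
                         genes_a: Sequence[GeneModel],
                         genes_b: Sequence[GeneModel],
                         tied_a: set[str] | None = None) -> list[RBHPair]:
    """Pairs (a, b) with ``map_ab[a] == b`` and ``map_ba[b] == a``.

    Ranks come from sorting each genome's genes by (chromosome, start);
    pairs are returned sorted by ``rank_a``.
    """
    ranks_a = gene_ranks(genes_a)
    ranks_b = gene_ranks(genes_b)
    pairs = []
    for a, b in map_ab.items():
        if map_ba.get(b) != a:
            continue
        if a not in ranks_a:
            raise ValidationError(f"gene {a!r} has no position in genome A")
        if b not in ranks_b:
            raise ValidationError(f"gene {b!r} has no position in genome B")
        ra, ca = ranks_a[a]
        rb, cb = ranks_b[b]
        pairs.append(RBHPair(gene_a=a, gene_b=b, rank_a=ra, rank_b=rb,
                             chrom_a=ca, chrom_b=cb,
                             tied_best=bool(tied_a and a in tied_a)))
    pairs.sort(key=lambda p: p.rank_a)
    return pairs


def detect_synteny_outliers(pairs: Sequence[RBHPair], window: int = 5,
                            tolerance: int = 20) -> list[bool]:
    """Flag pairs whose partner rank deviates from their flanking context.

    For each pair the median partner rank of up to ``window`` flanking
    pairs on each side (the pair itself excluded) is taken; the pair is an
    outlier iff its partner rank deviates by more than ``tolerance`` ranks,
    or its partner chromosome differs from the flanking majority, or it
    sits in a local partner-rank reversal (the partner rank decreases into
    and out of the pair) — the latter catches the interior of inversions
    too small to exceed the rank tolerance.  With fewer than 3 pairs
    nothing is flagged.
    """
    n = len(pairs)
    if n < 3:
        return [False] * n
    ranks_b = np.array([p.rank_b for p in pairs])
    chroms_b = [p.chrom_b for p in pairs]
    decreasing = [ranks_b[i + 1] < ranks_b[i] and chroms_b[i] == chroms_b[i + 1]
                  for i in range(n - 1)]
    flags = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        idx = [j for j in range(lo, hi) if j != i]
        med = float(np.median(ranks_b[idx]))
        chrom_counts: dict[str, int] = {}
        for j in idx:
            chrom_counts[chroms_b[j]] = chrom_counts.get(chroms_b[j], 0) + 1
        majority = max(sorted(chrom_counts), key=lambda c: chrom_counts[c])
        reversal = 0 < i < n - 1 and decreasing[i - 1] and decreasing[i]
        flags.append(abs(ranks_b[i] - med) > tolerance
                     or chroms_b[i] != majority or reversal)
    return flags


def call_sv_blocks(pairs: Sequence[RBHPair], outlier_flags: Sequence[bool],
                   min_run: int = 3) -> list[SyntenyBlockCall]:
    """Call maximal monotone runs of >= min_run consecutive outlier pairs.

    Consecutive means adjacent in the rank_a-sorted pair list.  Within an
    outlier run, maximal sub-runs with monotone partner ranks are taken;
    a strictly decreasing partner-rank run is an inversion, otherwise a
    translocation.
    """
    if len(pairs) != len(outlier_flags):
        raise ValidationError("pairs and outlier flags differ in length")
    blocks: list[SyntenyBlockCall] = []
    i = 0
    n = len(pairs)
    while i < n:
        if not outlier_flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outlier_flags[j + 1]:
            j += 1
        # split the run [i, j] into maximal monotone segments
        k = i
        while k <= j:
            m = k
            direction = 0
            while m + 1 <= j:
                step = pairs[m + 1].rank_b - pairs[m].rank_b
                d = (step > 0) - (step < 0)
                if direction == 0:
                    direction = d
                elif d != 0 and d != direction:
                    break
                m += 1
            seg = tuple(pairs[k:m + 1])
            if len(seg) >= min_run:
                sv_type = "inversion" if direction < 0 else "translocation"
                blocks.append(SyntenyBlockCall(pairs=seg, sv_type=sv_type))
            k = m + 1
        i = j + 1
    return blocks
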