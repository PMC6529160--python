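"""Non-redundant TE annotation from library hits and TE-gene flagging.

A TE library mapped against the assembly yields many overlapping hits; hits
scoring at least 90% of the library element's own top score (from its
mapping against the reference the library derives from) are kept and
resolved greedily by descending score into a non-overlapping placement set.
Protein-coding genes whose span is covered by TE placements over more than
80% are flagged as putative TE genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneModel, Hit, ValidationError


@dataclass(frozen=True)
class TEPlacement:
    te_id: str
    seq_id: str
    start: int          # 0-based half-open
    end: int
    score: float

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(f"TE {self.te_id}: invalid interval")


@dataclass(frozen=True)
class TEGeneFlag:
    gene_id: str
    te_fraction: float
    flagged: bool


def select_te_placements(hits: Sequence[Hit], top_scores: Mapping[str, float],
                         min_frac: float = 0.9) -> list[TEPlacement]:
    """Score-filter TE hits and resolve overlaps greedily by score.

    Hits with ``bitscore >= min_frac * top_score`` are candidates
    (inclusive at the cutoff); candidates are accepted in order of
    descending bitscore (ties: longer alignment, then lexicographic te_id)
    and discarded when they overlap an already-accepted placement by
    >= 1 bp.  Overlap is strand-agnostic.
    """
    candidates = []
    for h in hits:
        if h.query_id not in top_scores:
            raise ValidationError(f"TE {h.query_id!r} has no top score")
        if h.bitscore >= min_frac * top_scores[h.query_id]:
            start, end = h.subject_interval()
            candidates.append(TEPlacement(te_id=h.query_id, seq_id=h.subject_id,
                                          start=start, end=end, score=h.bitscore))
    candidates.sort(key=lambda p: (-p.score, -(p.end - p.start), p.te_id,
                                   p.seq_id, p.start))
    accepted: list[TEPlacement] = []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for p in candidates:
        ivs = by_seq.setdefault(p.seq_id, [])
        if any(p.start < e and s < p.end for s, e in ivs):
            continue
        ivs.append((p.start, p.end))
        accepted.append(p)
    accepted.sort(key=lambda p: (p.seq_id, p.start, p.te_id))
    return accepted


def _union_overlap(start: int, end: int,
                   intervals: Sequence[tuple[int, int]]) -> int:
    """Bases of [start, end) covered by the union of sorted intervals."""
    covered = 0
    cursor = start
    for s, e in intervals:
        if e <= cursor:
            continue
        if s >= end:
            break
        covered += min(e, end) - max(s, cursor)
        cursor = max(cursor, e)
        if cursor >= end:
            break
    return covered


def flag_te_genes(genes: Sequence[GeneModel], placements: Sequence[TEPlacement],
                  min_frac: float = 0.8, exons_only: bool = False
                  ) -> list[TEGeneFlag]:
    """Flag genes whose span is TE-covered over strictly more than min_frac.

    ``te_fraction`` is the union-covered share of the gene span (or, with
    ``exons_only``, of the exonic bases).
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for p in sorted(placements, key=lambda p: (p.seq_id, p.start)):
        by_seq.setdefault(p.seq_id, []).append((p.start, p.end))

    flags = []
    for g in genes:
        ivs = by_seq.get(g.seq_id, [])
        if exons_only and g.exons:
            spans = g.exons
        else:
            spans = ((g.start, g.end),)
        total = sum(e - s for s, e in spans)
        covered = sum(_union_overlap(s, e, ivs) for s, e in spans)
        frac = covered / total if total else 0.0
        flags.append(TEGeneFlag(gene_id=g.gene_id, te_fraction=frac,
                                flagged=frac > min_frac))
    return flags
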