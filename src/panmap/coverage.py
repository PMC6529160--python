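"""Per-gene relative read coverage and two-accession duplication calls.

Copy-number differences between two accessions are read off mapped depth:
reads of both accessions are mapped to one reference assembly, per-gene
median depth is normalised twice (to the accession-wide median depth, then
to the per-gene median across genes) and the two accessions' values are
compared with hard ratio cutoffs.  All medians make the statistic robust to
coverage outliers and free of any scale, so calls are invariant under
rescaling either accession's depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack, GeneModel, ValidationError


@dataclass(frozen=True)
class GeneCoverageValue:
    gene_id: str
    raw_median_depth: float
    relative_coverage: float


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    call: str        # duplicated_in_Q | duplicated_in_R | balanced | uncallable
    v_r: float
    v_q: float

    @property
    def ratio(self) -> float:
        """v_R / v_Q (inf when v_Q is 0 and v_R > 0, nan when both are 0)."""
        if self.v_q > 0:
            return self.v_r / self.v_q
        return float("inf") if self.v_r > 0 else float("nan")


def gene_relative_coverage(track: CoverageTrack,
                           genes: Sequence[GeneModel]) -> list[GeneCoverageValue]:
    """Doubly-normalised per-gene coverage for one accession.

    Step 1: median depth over all positions in each gene span (introns
    included, zero-depth positions included).  Step 2: divide by the
    accession-wide per-position median depth.  Step 3: divide by the median
    of the step-2 values over genes with nonzero value, so the per-gene
    median of nonzero relative coverages is exactly 1.
    """
    if not genes:
        raise ValidationError("empty gene list")
    for g in genes:
        if g.seq_id not in track.depths:
            raise ValidationError(f"gene {g.gene_id} on sequence {g.seq_id!r} "
                                  f"absent from track {track.accession_id!r}")
        if g.end > len(track.depths[g.seq_id]):
            raise ValidationError(f"gene {g.gene_id} extends past {g.seq_id!r}")

    genome_median = float(np.median(track.genome_concat()))
    if genome_median <= 0:
        raise ValidationError("accession-wide median depth is zero")

    raw = np.array([float(np.median(track.depths[g.seq_id][g.start:g.end]))
                    for g in genes])
    step2 = raw / genome_median
    nonzero = step2[step2 > 0]
    if nonzero.size == 0:
        raise ValidationError("all genes have zero median depth")
    per_gene_median = float(np.median(nonzero))
    rel = step2 / per_gene_median
    return [GeneCoverageValue(g.gene_id, float(r), float(v))
            for g, r, v in zip(genes, raw, rel)]


def classify_duplications(values_r: Sequence[GeneCoverageValue],
                          values_q: Sequence[GeneCoverageValue],
                          low: float = 0.5, high: float = 1.5
                          ) -> list[DuplicationCall]:
    """Classify genes by the ratio of relative coverages between accessions.

    R is the accession whose assembly was the mapping reference, Q the
    other.  Strict inequalities: a gene is duplicated in Q iff
    ``v_R < low * v_Q`` and duplicated in R iff ``v_R > high * v_Q``;
    values exactly on a boundary are balanced.  Both values zero is
    uncallable.
    """
    map_r = {v.gene_id: v for v in values_r}
    map_q = {v.gene_id: v for v in values_q}
    if set(map_r) != set(map_q):
        raise ValidationError("gene universes of the two accessions differ")
    calls = []
    for gid in map_r:
        v_r, v_q = map_r[gid].relative_coverage, map_q[gid].relative_coverage
        if v_r == 0 and v_q == 0:
            call = "uncallable"
        elif v_q == 0:
            call = "duplicated_in_R"
        elif v_r < low * v_q:
            call = "duplicated_in_Q"
        elif v_r > high * v_q:
            call = "duplicated_in_R"
        else:
            call = "balanced"
        calls.append(DuplicationCall(gene_id=gid, call=call, v_r=v_r, v_q=v_q))
    return calls


def filter_te_calls(calls: Iterable[DuplicationCall],
                    te_flags: Mapping[str, bool]) -> list[DuplicationCall]:
    """Drop duplication calls for TE-flagged genes from the duplicated sets."""
    out = []
    for c in calls:
        if c.call in ("duplicated_in_Q", "duplicated_in_R") and te_flags.get(c.gene_id):
            continue
        out.append(c)
    return out
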