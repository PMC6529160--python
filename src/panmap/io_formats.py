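"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Everything held in memory is 0-based half-open ``[start, end)``.  Everything
written to or read from disk follows the dialect of the respective format:
GFF3, AGP and per-base depth TSV are 1-based inclusive; BED is 0-based
half-open; BLAST tabular carries 1-based inclusive coordinates with
minus-strand subject placements encoded as ``sstart > send``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(ValueError):
    """Structurally valid input that violates a semantic constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A named genomic interval with strand and exon structure.

    Coordinates are 0-based half-open.  ``exons`` are sorted, non-overlapping
    sub-intervals of ``[start, end)``; an empty exon list denotes a gene whose
    exon structure is unknown (the whole span is then treated as exonic).
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = None
        for (a, b) in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{a}, {b}) outside gene span")
            if prev_end is not None and a < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = b

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Hit:
    """One row of a 12-column BLAST tabular (``-outfmt 6``) hit table.

    ``subject_start > subject_end`` is preserved as read and means a
    minus-strand placement on the subject.  Coordinates are kept 1-based
    inclusive exactly as in the file; use :meth:`subject_interval` for the
    0-based half-open span.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.align_len <= 0:
            raise ValidationError("align_len must be > 0")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValidationError("bitscore and evalue must be >= 0")

    @property
    def subject_strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"

    def subject_interval(self) -> tuple[int, int]:
        """Subject placement as a 0-based half-open interval."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return lo - 1, hi


@dataclass
class CoverageTrack:
    """Per-base read depth for one accession mapped to one assembly."""

    accession_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for seq_id, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValidationError(f"{seq_id}: depth array must be 1-D")
            if np.any(arr < 0):
                raise ValidationError(f"{seq_id}: negative depth")
            self.depths[seq_id] = arr.astype(np.int64, copy=False)

    def genome_concat(self) -> np.ndarray:
        """All per-position depths concatenated in sorted sequence order."""
        keys = sorted(self.depths)
        return np.concatenate([self.depths[k] for k in keys]) if keys else np.array([], dtype=np.int64)


@dataclass(frozen=True)
class AgpRecord:
    """One AGP v2.1 line: a contig (W) or gap (U) component of an object.

    Coordinates are internal 0-based half-open; they are converted to the
    1-based inclusive AGP convention on write.
    """

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # W or U
    component_id: str | None = None   # W only
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None    # W only
    gap_length: int | None = None     # U only

    def __post_init__(self):
        if self.component_type not in ("W", "U"):
            raise ValidationError(f"unsupported component type {self.component_type!r}")
        if self.component_type == "W":
            if self.component_id is None or self.orientation not in ("+", "-"):
                raise ValidationError("W record needs component_id and +/- orientation")
        else:
            if self.gap_length is None or self.gap_length <= 0:
                raise ValidationError("U record needs a positive gap_length")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(stream: IO[str]) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 stream.

    Exons may point at the gene directly or through an intermediate mRNA
    (``exon -> Parent=mRNA -> Parent=gene``); only ID/Parent attributes are
    interpreted.  Returned genes are sorted by ``(seq_id, start)`` with
    coordinates converted to 0-based half-open.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[int, str, int, int]] = []  # line_no, parent, start, end

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", line_no)
        seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", line_no) from None
        if start1 < 1 or end1 < start1:
            raise ParseError(f"invalid GFF3 coordinates {start1}..{end1}", line_no)
        attrs = _gff3_attributes(attrs_s)
        ftype = ftype.lower()
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise ParseError("gene feature without ID attribute", line_no)
            if gid in genes:
                raise ParseError(f"duplicate gene ID {gid!r}", line_no)
            genes[gid] = dict(seq_id=seq_id, start=start1 - 1, end=end1,
                              strand=strand if strand in "+-" else "+", exons=[])
        elif ftype == "mrna":
            mid, parent = attrs.get("ID"), attrs.get("Parent")
            if mid and parent:
                mrna_parent[mid] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise ParseError("exon feature without Parent attribute", line_no)
            pending_exons.append((line_no, parent, start1 - 1, end1))

    for line_no, parent, start0, end0 in pending_exons:
        gid = mrna_parent.get(parent, parent)
        gid = mrna_parent.get(gid, gid)
        if gid not in genes:
            raise ValidationError(
                f"line {line_no}: exon Parent {parent!r} resolves to no gene")
        g = genes[gid]
        if not (g["start"] <= start0 < end0 <= g["end"]):
            raise ValidationError(
                f"line {line_no}: exon [{start0}, {end0}) outside gene {gid!r}")
        g["exons"].append((start0, end0))

    models = []
    for gid, g in genes.items():
        exons = sorted(set(g.pop("exons")))
        models.append(GeneModel(gene_id=gid, exons=tuple(exons), **g))
    models.sort(key=lambda m: (m.seq_id, m.start, m.gene_id))
    return models


def write_gene_models(models: Iterable[GeneModel], stream: IO[str]) -> None:
    """Write gene (and exon) features as GFF3, 1-based inclusive."""
    stream.write("##gff-version 3\n")
    for m in sorted(models, key=lambda m: (m.seq_id, m.start, m.gene_id)):
        stream.write("\t".join([m.seq_id, "panmap", "gene", str(m.start + 1),
                                str(m.end), ".", m.strand, ".", f"ID={m.gene_id}"]) + "\n")
        for i, (a, b) in enumerate(m.exons, start=1):
            stream.write("\t".join([m.seq_id, "panmap", "exon", str(a + 1), str(b),
                                    ".", m.strand, ".",
                                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# per-base depth TSV
# ---------------------------------------------------------------------------

def read_depth_track(stream: IO[str], seq_lengths: Mapping[str, int],
                     accession_id: str = "") -> CoverageTrack:
    """Read a sparse (seq_id, 1-based position, depth) TSV into dense arrays.

    Positions absent from the file get depth 0; a position beyond the
    declared sequence length is a validation error.
    """
    depths = {sid: np.zeros(int(n), dtype=np.int64) for sid, n in seq_lengths.items()}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns, got {len(fields)}", line_no)
        sid, pos_s, depth_s = fields
        if sid not in depths:
            raise ValidationError(f"line {line_no}: unknown sequence {sid!r}")
        try:
            pos, depth = int(pos_s), int(depth_s)
        except ValueError:
            raise ParseError("non-integer position or depth", line_no) from None
        if not 1 <= pos <= len(depths[sid]):
            raise ValidationError(
                f"line {line_no}: position {pos} outside {sid!r} (length {len(depths[sid])})")
        if depth < 0:
            raise ValidationError(f"line {line_no}: negative depth")
        depths[sid][pos - 1] = depth
    return CoverageTrack(accession_id=accession_id, depths=depths)


def write_depth_track(track: CoverageTrack, stream: IO[str],
                      sparse: bool = True) -> None:
    """Write a depth track as (seq_id, 1-based position, depth) TSV."""
    for sid in sorted(track.depths):
        arr = track.depths[sid]
        if sparse:
            (idx,) = np.nonzero(arr)
        else:
            idx = np.arange(len(arr))
        for i in idx:
            stream.write(f"{sid}\t{i + 1}\t{arr[i]}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_HIT_FIELDS = [f.name for f in dataclasses.fields(Hit)]


def read_hit_table(stream: IO[str]) -> list[Hit]:
    """Parse 12-column BLAST ``-outfmt 6`` rows into :class:`Hit` objects."""
    hits = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ParseError(f"expected 12 tab-separated columns, got {len(fields)}", line_no)
        try:
            hit = Hit(
                query_id=fields[0], subject_id=fields[1],
                percent_identity=float(fields[2]), align_len=int(fields[3]),
                mismatches=int(fields[4]), gap_opens=int(fields[5]),
                query_start=int(fields[6]), query_end=int(fields[7]),
                subject_start=int(fields[8]), subject_end=int(fields[9]),
                evalue=float(fields[10]), bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise ParseError(str(exc), line_no) from None
        hits.append(hit)
    return hits


def _fmt_float(x: float) -> str:
    return format(x, "g")


def write_hit_table(hits: Iterable[Hit], stream: IO[str]) -> None:
    for h in hits:
        stream.write("\t".join([
            h.query_id, h.subject_id, _fmt_float(h.percent_identity),
            str(h.align_len), str(h.mismatches), str(h.gap_opens),
            str(h.query_start), str(h.query_end),
            str(h.subject_start), str(h.subject_end),
            _fmt_float(h.evalue), _fmt_float(h.bitscore),
        ]) + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

def build_agp(object_id: str,
              components: Sequence[tuple[str, int, str]],
              gap_length: int = 100) -> list[AgpRecord]:
    """Tile contigs (id, length, orientation) into AGP records for one object.

    U gap records of ``gap_length`` are placed between consecutive contigs.
    """
    seen = set()
    records: list[AgpRecord] = []
    pos = 0
    part = 0
    for i, (cid, clen, orient) in enumerate(components):
        if cid in seen:
            raise ValidationError(f"duplicate component {cid!r} in object {object_id!r}")
        seen.add(cid)
        if clen <= 0:
            raise ValidationError(f"component {cid!r} has non-positive length")
        if i > 0:
            part += 1
            records.append(AgpRecord(object_id, pos, pos + gap_length, part, "U",
                                     gap_length=gap_length))
            pos += gap_length
        part += 1
        records.append(AgpRecord(object_id, pos, pos + clen, part, "W",
                                 component_id=cid, component_start=0,
                                 component_end=clen, orientation=orient))
        pos += clen
    return records


def write_agp(records: Iterable[AgpRecord], stream: IO[str]) -> None:
    """Write AGP v2.1; object/component coordinates become 1-based inclusive."""
    stream.write("##agp-version\t2.1\n")
    last_end: dict[str, int] = {}
    for r in records:
        if r.object_start != last_end.get(r.object_id, 0):
            raise ValidationError(
                f"object {r.object_id!r}: records do not tile contiguously at "
                f"{r.object_start}")
        last_end[r.object_id] = r.object_end
        if r.component_type == "W":
            cols = [r.object_id, str(r.object_start + 1), str(r.object_end),
                    str(r.part_number), "W", r.component_id,
                    str(r.component_start + 1), str(r.component_end), r.orientation]
        else:
            cols = [r.object_id, str(r.object_start + 1), str(r.object_end),
                    str(r.part_number), "U", str(r.gap_length),
                    "scaffold", "yes", "paired-ends"]
        stream.write("\t".join(cols) + "\n")


def read_agp(stream: IO[str]) -> list[AgpRecord]:
    records = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"expected 9 AGP columns, got {len(fields)}", line_no)
        obj, ostart, oend, part, ctype = fields[:5]
        try:
            if ctype == "W":
                rec = AgpRecord(obj, int(ostart) - 1, int(oend), int(part), "W",
                                component_id=fields[5],
                                component_start=int(fields[6]) - 1,
                                component_end=int(fields[7]),
                                orientation=fields[8])
            elif ctype in ("U", "N"):
                rec = AgpRecord(obj, int(ostart) - 1, int(oend), int(part), "U",
                                gap_length=int(fields[5]))
            else:
                raise ParseError(f"unsupported component type {ctype!r}", line_no)
        except ValueError as exc:
            raise ParseError(str(exc), line_no) from None
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path_or_stream) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{seq_id: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_stream, "fasta")}


def write_fasta(sequences: Mapping[str, str], path_or_stream, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in sequences.items()]
    SeqIO.write(records, path_or_stream, "fasta")


def filter_contigs_by_length(sequences: Mapping[str, str],
                             min_length: int = 50_000) -> dict[str, str]:
    """Drop contigs shorter than ``min_length`` (assembly ingest filter)."""
    return {sid: s for sid, s in sequences.items() if len(s) >= min_length}
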