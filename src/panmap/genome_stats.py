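"""Genome-distribution statistics.

Two analyses: (1) clustering of large structural variants around
centromeres, quantified as the Spearman rank correlation between per-window
SV counts and the window's distance to the centromere; (2) homotetramer
enrichment in assembly sequences homologous to reference gaps, tested
against length-matched random control sequences with a Mann-Whitney U test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io_formats import Hit, ValidationError


@dataclass(frozen=True)
class SVRecord:
    seq_id: str
    start: int        # 0-based half-open
    end: int
    sv_type: str = ""

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValidationError("SV length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapHomolog:
    gap_id: str
    source_seq: str
    source_start: int
    source_end: int
    target_seq: str
    target_start: int
    target_end: int
    sequence: str


def window_sv_counts(svs: Sequence[SVRecord], seq_lengths: Mapping[str, int],
                     centromeres: Mapping[str, int], window: int = 1_000_000,
                     min_len: int = 1000) -> pd.DataFrame:
    """Per-window SV counts and window distance to the centromere.

    SVs with ``length >= min_len`` are assigned to the fixed non-overlapping
    ``window``-sized tile containing their start; the distance is
    |window midpoint - centromere midpoint|.
    """
    rows = []
    for sid in sorted(seq_lengths):
        if sid not in centromeres:
            raise ValidationError(f"no centromere position for {sid!r}")
        n_win = int(np.ceil(seq_lengths[sid] / window))
        for w in range(n_win):
            mid = w * window + min(window, seq_lengths[sid] - w * window) / 2
            rows.append({"seq_id": sid, "window_start": w * window,
                         "count": 0,
                         "centromere_distance": abs(mid - centromeres[sid])})
    table = pd.DataFrame(rows).set_index(["seq_id", "window_start"])
    for sv in svs:
        if sv.seq_id not in seq_lengths:
            raise ValidationError(f"SV on unknown sequence {sv.seq_id!r}")
        if sv.length < min_len:
            continue
        w = (sv.start // window) * window
        table.loc[(sv.seq_id, w), "count"] += 1
    return table.reset_index()


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; t-approx p.

    Returns (nan, nan) for a constant vector, where the coefficient is
    undefined.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = _st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def find_assembly_gaps(sequence: str, min_run: int = 10) -> list[tuple[int, int]]:
    """Maximal N/n runs of length >= min_run, 0-based half-open."""
    return [(m.start(), m.end())
            for m in re.finditer(f"[Nn]{{{min_run},}}", sequence)]


def extract_gap_homologs(gaps: Mapping[str, tuple[str, int, int]],
                         flank_hits: Sequence[Hit],
                         target: Mapping[str, str],
                         max_span: int = 200_000
                         ) -> tuple[list[GapHomolog], dict[str, str]]:
    """Extract target sequences enclosed by best hits of gap-flank pairs.

    ``gaps`` maps gap_id -> (source_seq, start, end); ``flank_hits`` carries
    queries named ``<gap_id>_left`` / ``<gap_id>_right``.  A gap is spanned
    iff both flanks' best hits are on one target sequence, same strand, in
    consistent order, and the enclosed span (between the inner hit
    boundaries) is positive and <= ``max_span``.  Minus-strand homologs are
    reverse-complemented into source orientation.  Returns (homologs,
    rejected-with-reason).
    """
    from Bio.Seq import Seq

    best: dict[str, Hit] = {}
    for h in flank_hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < \
                (-cur.bitscore, cur.evalue, cur.subject_id):
            best[h.query_id] = h

    homologs: list[GapHomolog] = []
    rejected: dict[str, str] = {}
    for gap_id in sorted(gaps):
        src_seq, src_start, src_end = gaps[gap_id]
        left = best.get(f"{gap_id}_left")
        right = best.get(f"{gap_id}_right")
        if left is None or right is None:
            rejected[gap_id] = "missing flank hit"
            continue
        if left.subject_id != right.subject_id:
            rejected[gap_id] = "flanks hit different sequences"
            continue
        if left.subject_strand != right.subject_strand:
            rejected[gap_id] = "flanks hit opposite strands"
            continue
        l_lo, l_hi = left.subject_interval()
        r_lo, r_hi = right.subject_interval()
        if left.subject_strand == "+":
            inner_start, inner_end = l_hi, r_lo
        else:
            inner_start, inner_end = r_hi, l_lo
        if inner_end <= inner_start:
            rejected[gap_id] = "flank hits in inconsistent order"
            continue
        if inner_end - inner_start > max_span:
            rejected[gap_id] = f"enclosed span {inner_end - inner_start} exceeds max"
            continue
        seq = target[left.subject_id][inner_start:inner_end]
        if left.subject_strand == "-":
            seq = str(Seq(seq).reverse_complement())
        homologs.append(GapHomolog(gap_id=gap_id, source_seq=src_seq,
                                   source_start=src_start, source_end=src_end,
                                   target_seq=left.subject_id,
                                   target_start=inner_start,
                                   target_end=inner_end, sequence=seq))
    return homologs, rejected


def homotetramer_count(sequence: str, mode: str = "overlapping") -> int:
    """Number of homotetramer occurrences (four identical bases in a row).

    Overlapping convention: every position i with s[i]=s[i+1]=s[i+2]=s[i+3]
    counts, so a run of length L >= 4 contributes L - 3.  The alternative
    ``mode='runs'`` counts each maximal run >= 4 once.  Case-insensitive;
    positions involving N never count.
    """
    if mode not in ("overlapping", "runs"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    s = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if len(s) < 4:
        return 0
    valid = s != ord("N")
    eq = (s[:-1] == s[1:]) & valid[:-1] & valid[1:]
    tet = eq[:-2] & eq[1:-1] & eq[2:]
    if mode == "overlapping":
        return int(tet.sum())
    # a run is counted once, at the first of its tetramer positions
    run_starts = tet.copy()
    run_starts[1:] &= ~tet[:-1]
    return int(run_starts.sum())


def homotetramer_frequency(sequence: str, mode: str = "overlapping") -> float:
    """Homotetramer occurrences per kbp of sequence."""
    if not sequence:
        raise ValidationError("empty sequence")
    return homotetramer_count(sequence, mode=mode) / len(sequence) * 1000.0


def mann_whitney_u(a: Sequence[float], b: Sequence[float]
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: (U of sample a, p).

    Exact enumeration when n_a + n_b <= 12 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def sample_control_sequences(assembly: Mapping[str, str],
                             lengths: Sequence[int],
                             rng: np.random.Generator,
                             exclude: Mapping[str, Sequence[tuple[int, int]]]
                             | None = None,
                             max_tries: int = 1000) -> list[str]:
    """Length-matched random sequences avoiding N runs and excluded spans."""
    exclude = exclude or {}
    seq_ids = sorted(assembly)
    weights = np.array([len(assembly[s]) for s in seq_ids], dtype=float)
    weights /= weights.sum()
    out = []
    for length in lengths:
        for _ in range(max_tries):
            sid = seq_ids[int(rng.choice(len(seq_ids), p=weights))]
            seq = assembly[sid]
            if len(seq) < length:
                continue
            start = int(rng.integers(0, len(seq) - length + 1))
            end = start + length
            if any(start < e and s < end for s, e in exclude.get(sid, ())):
                continue
            picked = seq[start:end]
            if "N" in picked or "n" in picked:
                continue
            out.append(picked)
            break
        else:
            raise ValidationError(f"no N-free placement found for length {length}")
    return out
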