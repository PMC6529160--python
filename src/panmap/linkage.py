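"""Genetic-linkage anchoring of contigs into pseudochromosomes.

An F2 intercross between two inbred accessions yields, for every plant, two
independent recombinant gametes.  Genotype calls at PCR markers (A = homozygous
first parent, H = heterozygous, B = homozygous second parent) let us estimate
the recombination fraction r between marker pairs, group marker-bearing
contigs into linkage groups, order and orient the contigs within each group,
and finally concatenate them into pseudochromosome sequences.

The recombination fraction is estimated by maximum likelihood under the
standard F2 model: the nine two-marker genotype classes are products of two
independent gamete transmissions, and the double-heterozygote class is a
mixture of the parental (both gametes non-recombinant) and recombinant (both
gametes recombinant) phases.  The likelihood is maximised by EM on the
expected number of recombinant gametes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from Bio.Seq import Seq

from .io_formats import AgpRecord, ValidationError, build_agp

MISSING = -1
_CODE_TO_CALL = {0: "A", 1: "H", 2: "B", MISSING: "-"}
_CALL_TO_CODE = {"A": 0, "H": 1, "B": 2, "-": MISSING, "N": MISSING, ".": MISSING}

#: recombinant gametes implied by each unambiguous two-marker genotype class;
#: the double heterozygote (1,1) is phase-ambiguous and handled separately.
_REC_GAMETES = np.array([[0, 1, 2],
                         [1, 0, 1],   # [1,1] entry unused
                         [2, 1, 0]], dtype=float)


@dataclass(frozen=True)
class Marker:
    """A genotyped marker: its physical home and (optionally) true map info."""

    marker_id: str
    contig_id: str
    position: int                     # bp on the contig, 0-based
    linkage_group: str | None = None  # truth/annotation, not used by estimators
    cm: float | None = None           # true genetic position, if known


@dataclass
class GenotypeMatrix:
    """F2 plants x markers with calls in {A, H, B, missing}.

    Calls are stored as an int8 array with codes 0/1/2 and -1 for missing.
    """

    plants: list[str]
    markers: list[Marker]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.plants), len(self.markers)):
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.plants)} plants x {len(self.markers)} markers")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("genotype codes must be in {0,1,2,-1}")

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.marker_ids.index(marker_id)]

    def to_frame(self) -> pd.DataFrame:
        letters = np.vectorize(_CODE_TO_CALL.get)(self.codes)
        return pd.DataFrame(letters, index=self.plants, columns=self.marker_ids)

    def write_tsv(self, stream: IO[str]) -> None:
        self.to_frame().to_csv(stream, sep="\t", index_label="plant")

    @classmethod
    def read_tsv(cls, stream: IO[str], markers: Sequence[Marker]) -> "GenotypeMatrix":
        df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str)
        by_id = {m.marker_id: m for m in markers}
        try:
            ordered = [by_id[c] for c in df.columns]
        except KeyError as exc:
            raise ValidationError(f"genotype column {exc} has no marker metadata")
        codes = df.map(lambda v: _CALL_TO_CODE.get(str(v).strip(), MISSING)).to_numpy()
        return cls(plants=[str(p) for p in df.index], markers=ordered,
                   codes=codes.astype(np.int8))


@dataclass(frozen=True)
class RecombinationEstimate:
    marker_1: str
    marker_2: str
    r_hat: float
    n_informative: int          # plants with calls at both markers
    loglik: float
    degenerate: bool = False
    # phase-unambiguous counting statistics (all classes except double-het):
    rec_gametes: int = 0        # recombinant gametes among unambiguous plants
    n_gametes_unambiguous: int = 0
    rec_plants: int = 0         # unambiguous plants with >= 1 recombinant gamete


def _class_counts(calls_1: np.ndarray, calls_2: np.ndarray) -> np.ndarray:
    ok = (calls_1 != MISSING) & (calls_2 != MISSING)
    a, b = calls_1[ok], calls_2[ok]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return counts


def _f2_loglik(counts: np.ndarray, r: float) -> float:
    r = min(max(r, 0.0), 1.0)
    p = np.empty((3, 3))
    pp, rr, pr = ((1 - r) / 2) ** 2, (r / 2) ** 2, r * (1 - r) / 2
    p[0, 0] = p[2, 2] = pp
    p[0, 2] = p[2, 0] = rr
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = pr
    p[1, 1] = ((1 - r) ** 2 + r ** 2) / 2
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return -np.inf
    return float((counts[mask] * logp[mask]).sum())


def estimate_rf(calls_1: np.ndarray, calls_2: np.ndarray,
                marker_1: str = "m1", marker_2: str = "m2",
                tol: float = 1e-6, max_iter: int = 200) -> RecombinationEstimate:
    """ML recombination fraction between two markers from paired F2 calls.

    Plants missing either call are excluded.  The likelihood is maximised
    over [0, 1] and the estimate folded (r -> 1 - r beyond 0.5), which makes
    it invariant under an allele-label swap at either marker (repulsion
    phase); the reported r_hat always lies in [0, 0.5].  A monomorphic
    marker yields r_hat = 0 with ``degenerate=True``.
    """
    calls_1 = np.asarray(calls_1, dtype=np.int8)
    calls_2 = np.asarray(calls_2, dtype=np.int8)
    counts = _class_counts(calls_1, calls_2)
    n = int(counts.sum())

    def _counting_stats():
        known = counts.astype(float).copy()
        known[1, 1] = 0.0
        rec_g = int((known * _REC_GAMETES).sum())
        n_unamb = int(n - counts[1, 1])
        rec_p = int(known[_REC_GAMETES >= 1].sum())
        return rec_g, 2 * n_unamb, rec_p

    mono_1 = len(np.unique(calls_1[calls_1 != MISSING])) < 2
    mono_2 = len(np.unique(calls_2[calls_2 != MISSING])) < 2
    if n == 0 or mono_1 or mono_2:
        rec_g, n_g, rec_p = _counting_stats()
        return RecombinationEstimate(marker_1, marker_2, 0.0, n,
                                     _f2_loglik(counts, 0.0) if n else 0.0,
                                     degenerate=True, rec_gametes=rec_g,
                                     n_gametes_unambiguous=n_g, rec_plants=rec_p)

    r = 0.25
    for _ in range(max_iter):
        if r <= 0.0:
            w = 0.0
        else:
            w = r * r / ((1 - r) ** 2 + r * r)
        known = counts.astype(float).copy()
        known[1, 1] = 0.0
        exp_rec = (known * _REC_GAMETES).sum() + counts[1, 1] * 2.0 * w
        r_new = min(max(exp_rec / (2.0 * n), 0.0), 1.0)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    loglik = _f2_loglik(counts, r)
    if r > 0.5:         # fold a repulsion-phase estimate back to [0, 0.5]
        r = 1.0 - r
    if r < 1e-8:        # snap a numerically-converged boundary estimate
        r = 0.0

    rec_g, n_g, rec_p = _counting_stats()
    return RecombinationEstimate(marker_1, marker_2, float(r), n,
                                 loglik, degenerate=False,
                                 rec_gametes=rec_g, n_gametes_unambiguous=n_g,
                                 rec_plants=rec_p)


def rf_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric marker x marker matrix of ML recombination fractions."""
    ids = matrix.marker_ids
    if len(ids) < 2:
        raise ValidationError("need at least 2 markers")
    out = np.zeros((len(ids), len(ids)))
    for i, j in itertools.combinations(range(len(ids)), 2):
        est = estimate_rf(matrix.codes[:, i], matrix.codes[:, j])
        # degenerate pairs carry no linkage information
        out[i, j] = out[j, i] = np.nan if est.degenerate else est.r_hat
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# grouping, ordering, orientation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    linkage_group: str
    order_index: int
    orientation: str              # '+', '-' or '?' (unknown)
    markers: tuple[str, ...] = ()


def _contig_distance(rf: pd.DataFrame, markers_a: Sequence[str],
                     markers_b: Sequence[str]) -> float:
    sub = rf.loc[list(markers_a), list(markers_b)].to_numpy()
    vals = sub[~np.isnan(sub)]
    return float(vals.min()) if vals.size else np.inf


def cluster_linkage_groups(rf: pd.DataFrame, marker_contigs: Mapping[str, str],
                           r_max: float = 0.25
                           ) -> tuple[list[list[str]], list[str]]:
    """Single-linkage clustering of contigs by minimum inter-marker r-hat.

    Returns (groups, unplaced); contigs without any marker in ``rf`` are
    reported unplaced.  Contigs join a group iff some marker pair between
    them has r-hat < ``r_max``.
    """
    contig_markers: dict[str, list[str]] = {}
    for m in rf.index:
        if m in marker_contigs:
            contig_markers.setdefault(marker_contigs[m], []).append(m)
    unplaced = sorted(set(marker_contigs.values()) - set(contig_markers))
    contigs = sorted(contig_markers)
    parent = {c: c for c in contigs}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for c1, c2 in itertools.combinations(contigs, 2):
        d = _contig_distance(rf, contig_markers[c1], contig_markers[c2])
        if d < r_max:
            parent[find(c1)] = find(c2)

    groups: dict[str, list[str]] = {}
    for c in contigs:
        groups.setdefault(find(c), []).append(c)
    out = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    return out, unplaced


def _best_order(contigs: list[str], dist: dict[tuple[str, str], float],
                exhaustive_limit: int = 8) -> list[str]:
    if len(contigs) <= 1:
        return list(contigs)

    def cost(path):
        return sum(dist[(path[i], path[i + 1])] for i in range(len(path) - 1))

    if len(contigs) <= exhaustive_limit:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(contigs):
            if perm[0] > perm[-1]:      # mirror handled by its reverse
                continue
            c = cost(perm)
            if c < best_cost - 1e-12 or (abs(c - best_cost) <= 1e-12
                                         and (best is None or perm < best)):
                best, best_cost = perm, c
        return list(best)
    # greedy nearest-neighbour from the globally closest pair
    pair = min(((a, b) for a in contigs for b in contigs if a < b),
               key=lambda p: dist[p])
    path = list(pair)
    remaining = [c for c in contigs if c not in path]
    while remaining:
        ext = min(((side, c) for side in (0, -1) for c in remaining),
                  key=lambda sc: dist[(path[sc[0]], sc[1])])
        side, c = ext
        path.insert(0 if side == 0 else len(path), c)
        remaining.remove(c)
    if path[0] > path[-1]:
        path.reverse()
    return path


def order_and_orient(group: Sequence[str], rf: pd.DataFrame,
                     markers: Sequence[Marker], linkage_group: str = "LG"
                     ) -> list[ContigPlacement]:
    """Order contigs by the minimal adjacent-r-hat path and orient them.

    Ordering is exhaustive for <= 8 contigs (greedy nearest-neighbour
    beyond); of the two mirror-image orders the one starting with the
    lexicographically smaller contig id is returned.  A contig's orientation
    is '+' when the physical order of its markers agrees with the genetic
    order implied by the flanking contigs, '-' when reversed, and '?' when
    the contig carries fewer than two markers.
    """
    group = sorted(group)
    contig_markers: dict[str, list[Marker]] = {c: [] for c in group}
    for m in markers:
        if m.contig_id in contig_markers and m.marker_id in rf.index:
            contig_markers[m.contig_id].append(m)
    for c in group:
        contig_markers[c].sort(key=lambda m: m.position)

    dist = {}
    for a, b in itertools.permutations(group, 2):
        dist[(a, b)] = _contig_distance(
            rf, [m.marker_id for m in contig_markers[a]],
            [m.marker_id for m in contig_markers[b]])
    order = _best_order(list(group), dist)

    placements = []
    for idx, cid in enumerate(order):
        ms = contig_markers[cid]
        orientation = "?"
        if len(ms) >= 2:
            # genetic distance of each marker to a flanking contig resolves
            # which physical end of the contig faces that neighbour
            if idx > 0:
                ref = [m.marker_id for m in contig_markers[order[idx - 1]]]
                sense = +1.0   # distance to the *previous* contig grows along '+'
            else:
                ref = [m.marker_id for m in contig_markers[order[idx + 1]]] \
                    if len(order) > 1 else []
                sense = -1.0   # distance to the *next* contig shrinks along '+'
            if ref:
                d = np.array([rf.loc[m.marker_id, ref].min() for m in ms])
                trend = sense * (d[-1] - d[0])
                if trend > 0:
                    orientation = "+"
                elif trend < 0:
                    orientation = "-"
        placements.append(ContigPlacement(
            contig_id=cid, linkage_group=linkage_group, order_index=idx,
            orientation=orientation,
            markers=tuple(m.marker_id for m in contig_markers[cid])))
    return placements


def anchor_contigs(matrix: GenotypeMatrix, r_max: float = 0.25
                   ) -> tuple[list[ContigPlacement], list[str], pd.DataFrame]:
    """Full anchoring: rf matrix -> groups -> ordered, oriented placements."""
    rf = rf_matrix(matrix)
    marker_contigs = {m.marker_id: m.contig_id for m in matrix.markers}
    groups, unplaced = cluster_linkage_groups(rf, marker_contigs, r_max=r_max)
    placements = []
    for i, group in enumerate(groups, start=1):
        placements.extend(order_and_orient(group, rf, matrix.markers,
                                           linkage_group=f"LG{i}"))
    return placements, unplaced, rf


# ---------------------------------------------------------------------------
# pseudochromosome construction
# ---------------------------------------------------------------------------

def build_pseudochromosomes(placements: Sequence[ContigPlacement],
                            contig_sequences: Mapping[str, str],
                            gap_length: int = 100,
                            reference_polarity: Mapping[str, str] | None = None
                            ) -> tuple[dict[str, str], list[AgpRecord]]:
    """Concatenate placed contigs into pseudochromosome sequences plus AGP.

    Minus-oriented contigs are reverse-complemented; unknown orientation is
    treated as '+'.  ``reference_polarity`` maps a linkage group to '-' to
    mirror the whole group (north-south convention transferred from an
    external reference).
    """
    by_group: dict[str, list[ContigPlacement]] = {}
    for p in placements:
        by_group.setdefault(p.linkage_group, []).append(p)

    fasta: dict[str, str] = {}
    agp: list[AgpRecord] = []
    for lg in sorted(by_group):
        plist = sorted(by_group[lg], key=lambda p: p.order_index)
        if reference_polarity and reference_polarity.get(lg) == "-":
            plist = [ContigPlacement(p.contig_id, p.linkage_group,
                                     len(plist) - 1 - p.order_index,
                                     {"+": "-", "-": "+"}.get(p.orientation, "?"),
                                     p.markers)
                     for p in reversed(plist)]
        parts, components = [], []
        for p in plist:
            if p.contig_id not in contig_sequences:
                raise ValidationError(f"missing sequence for contig {p.contig_id!r}")
            seq = contig_sequences[p.contig_id]
            orient = "-" if p.orientation == "-" else "+"
            parts.append(str(Seq(seq).reverse_complement()) if orient == "-" else seq)
            components.append((p.contig_id, len(seq), orient))
        fasta[lg] = ("N" * gap_length).join(parts)
        agp.extend(build_agp(lg, components, gap_length=gap_length))
    return fasta, agp


def reconstruct_from_agp(agp: Iterable[AgpRecord],
                         contig_sequences: Mapping[str, str]) -> dict[str, str]:
    """Rebuild object sequences from AGP records plus component sequences."""
    out: dict[str, list[str]] = {}
    for r in sorted(agp, key=lambda r: (r.object_id, r.object_start)):
        parts = out.setdefault(r.object_id, [])
        if r.component_type == "U":
            parts.append("N" * r.gap_length)
        else:
            seq = contig_sequences[r.component_id][r.component_start:r.component_end]
            parts.append(str(Seq(seq).reverse_complement())
                         if r.orientation == "-" else seq)
    return {k: "".join(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# recombination-rate comparison
# ---------------------------------------------------------------------------

def compare_recombination_rates(x1: int, n1: int, x2: int, n2: int,
                                correction: bool = True) -> tuple[float, float]:
    """Two-sample proportion test (Pearson chi-square, Yates-corrected).

    Equivalent to R's two-sample ``prop.test``: the 2x2 table of successes
    and failures is tested with one degree of freedom; the Yates term is
    capped at |O - E| so equal proportions give chi2 = 0, p = 1 exactly.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must satisfy 0 <= x <= n")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.array([[n1 * p_pool, n1 * (1 - p_pool)],
                         [n2 * p_pool, n2 * (1 - p_pool)]])
    delta = np.abs(observed - expected)
    yates = np.minimum(0.5, delta) if correction else 0.0
    stat = float((((delta - yates) ** 2) / expected).sum())
    return stat, float(_chi2_dist.sf(stat, df=1))
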