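"""Pan-genome gene classification from a panel relative-coverage matrix.

Across a panel of re-sequenced accessions mapped to one assembly, a gene
absent from an accession shows near-zero relative coverage there.  Genes
absent (< 0.1 relative coverage) from more than a threshold number of
accessions are dispensable; the remaining genes are TE genes when flagged
by the TE-overlap analysis, else core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_formats import ValidationError


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    gene_class: str          # core | dispensable | te
    n_absent: int            # accessions with relative coverage below `low`


def filter_accessions(matrix: pd.DataFrame, avg_depth: pd.Series,
                      min_avg_depth: float = 10.0) -> pd.DataFrame:
    """Drop accessions with average depth strictly below ``min_avg_depth``.

    The gene universe (rows) is unchanged; exactly-at-threshold accessions
    are retained.
    """
    missing = [a for a in matrix.columns if a not in avg_depth.index]
    if missing:
        raise ValidationError(f"accessions without average depth: {missing[:3]}")
    keep = [a for a in matrix.columns if avg_depth[a] >= min_avg_depth]
    if not keep:
        raise ValidationError("all accessions fall below the depth threshold")
    return matrix[keep]


def classify_genes(matrix: pd.DataFrame, te_flags: Mapping[str, bool],
                   low: float = 0.1, min_accessions: int = 100,
                   min_fraction: float | None = None) -> list[GeneClass]:
    """Partition genes into dispensable / te / core.

    A gene is dispensable iff its relative coverage is strictly below
    ``low`` in strictly more than ``min_accessions`` accessions (or more
    than ``min_fraction`` of them, when given — useful for small panels).
    Dispensable takes precedence over the TE flag; remaining genes are te
    when flagged, else core.
    """
    unknown = set(te_flags) - set(matrix.index)
    if unknown:
        raise ValidationError(f"TE flags reference unknown genes: {sorted(unknown)[:3]}")
    threshold = (min_fraction * matrix.shape[1]) if min_fraction is not None \
        else float(min_accessions)
    n_absent = (matrix < low).sum(axis=1)
    out = []
    for gid in matrix.index:
        n = int(n_absent[gid])
        if n > threshold:
            cls = "dispensable"
        elif te_flags.get(gid):
            cls = "te"
        else:
            cls = "core"
        out.append(GeneClass(gene_id=gid, gene_class=cls, n_absent=n))
    return out


def class_counts(classes: list[GeneClass]) -> dict[str, int]:
    counts = {"core": 0, "dispensable": 0, "te": 0}
    for c in classes:
        counts[c.gene_class] += 1
    return counts
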