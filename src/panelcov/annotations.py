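"""Per-gene annotation models and database representation tables.

Two annotation databases enter the audit: a broad "superset" (Known
Gene style: every transcript with protein evidence) and a conservative
"subset" (CCDS style: consensus coding regions, the basis of capture
kit designs).  Each gene's model is the union of all its transcripts'
coding exons collapsed to unique bases.  The representation table asks,
per gene and pooled over the panel, what fraction of the superset's
bases the subset retains — the ceiling on what a subset-designed
capture kit can even attempt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .intervals import (
    BedRecord,
    IntervalSet,
    contained_fraction,
    intersect,
    merge_intervals,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene symbol bound to its unique-base regions in one database."""

    gene: str
    regions: IntervalSet

    @property
    def size_bases(self) -> int:
        return self.regions.total_bases


@dataclass
class AnnotationDB:
    name: str
    models: dict[str, GeneModel]

    @property
    def genes(self) -> list[str]:
        return sorted(self.models)

    def pooled_regions(self) -> IntervalSet:
        """Union of all gene models; shared exons count once."""
        raw = [iv for m in self.models.values() for iv in m.regions]
        return merge_intervals(raw)


def build_db(records: list[BedRecord], name: str) -> AnnotationDB:
    """Group labeled intervals by gene symbol and collapse each group.

    Every record must carry a gene label; duplicate and overlapping
    records for one symbol collapse to unique bases (set semantics).
    """
    by_gene: dict[str, list] = {}
    for idx, (iv, label) in enumerate(records, 1):
        if label is None:
            raise ValueError(f"record {idx} ({iv.chrom}:{iv.start}-{iv.end}) has no gene label")
        by_gene.setdefault(label, []).append(iv)
    models = {g: GeneModel(g, merge_intervals(ivs)) for g, ivs in sorted(by_gene.items())}
    return AnnotationDB(name=name, models=models)


def enforce_nesting(subset_db: AnnotationDB, superset_db: AnnotationDB) -> AnnotationDB:
    """Clip each subset gene to its superset regions.

    Mirrors the preprocessing step that guarantees the conservative
    database is strictly contained in the broad one.  Genes absent from
    the superset — or left empty by clipping — are dropped with a
    warning.
    """
    models: dict[str, GeneModel] = {}
    for gene, model in subset_db.models.items():
        if gene not in superset_db.models:
            logger.warning("gene %s present only in %s; dropped", gene, subset_db.name)
            continue
        clipped = intersect(model.regions, superset_db.models[gene].regions)
        if clipped.total_bases == 0:
            logger.warning("gene %s has no bases inside %s; dropped", gene, superset_db.name)
            continue
        models[gene] = GeneModel(gene, clipped)
    return AnnotationDB(name=subset_db.name, models=models)


def representation_table(
    subset_db: AnnotationDB, superset_db: AnnotationDB, *, ensure_nested: bool = True
) -> pd.DataFrame:
    """Per-gene and pooled subset-in-superset base fractions.

    Returns one row per superset gene (columns ``gene``,
    ``subset_bases``, ``superset_bases``, ``fraction``) plus a final
    ``ALL`` row.  The ALL row pools unique bases across genes (union
    before counting) so shared exons are not double counted; it is not
    a mean of the per-gene fractions.
    """
    nested = enforce_nesting(subset_db, superset_db) if ensure_nested else subset_db
    rows = []
    for gene in superset_db.genes:
        sup = superset_db.models[gene].regions
        if sup.total_bases == 0:  # unreachable via build_db; guards hand-built DBs
            logger.warning("gene %s has zero superset bases; excluded", gene)
            continue
        sub = nested.models[gene].regions if gene in nested.models else IntervalSet()
        sub_in_sup = intersect(sub, sup)
        rows.append(
            {
                "gene": gene,
                "subset_bases": sub_in_sup.total_bases,
                "superset_bases": sup.total_bases,
                "fraction": contained_fraction(sub, sup),
            }
        )
    pooled_sub = nested.pooled_regions()
    pooled_sup = superset_db.pooled_regions()
    rows.append(
        {
            "gene": "ALL",
            "subset_bases": intersect(pooled_sub, pooled_sup).total_bases,
            "superset_bases": pooled_sup.total_bases,
            "fraction": contained_fraction(pooled_sub, pooled_sup),
        }
    )
    return pd.DataFrame(rows, columns=["gene", "subset_bases", "superset_bases", "fraction"])
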