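"""Selection and classification of retroviral intervals near cancer predisposition genes.

Cancer predisposition genes (CPGs) are first filtered on differential
expression; endogenous-retrovirus (HERV) and Alu intervals within a fixed
radius of the surviving gene bodies are then selected, merged into
non-overlapping target regions, and classified by their positional relation
to the gene (exonic / intronic / upstream / downstream).

All coordinates are 0-based half-open (BED convention); VCF positions are
converted on I/O.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap(self, other: "GenomicInterval") -> int | None:
        """Base-pair gap between two intervals; 0 if overlapping or bookended.

        Returns None for intervals on different chromosomes, for which a
        distance is undefined.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class CPGRecord:
    """A cancer predisposition gene with exon structure and DE statistics."""

    symbol: str
    body: GenomicInterval
    exons: list[GenomicInterval]
    log2_fold_change: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adjusted_p <= 1.0):
            raise ValueError(f"adjusted p must be in [0,1], got {self.adjusted_p}")
        for exon in self.exons:
            if exon.chrom != self.body.chrom or exon.start < self.body.start or exon.end > self.body.end:
                raise ValueError(
                    f"exon {exon} outside gene body of {self.symbol}"
                )


@dataclass
class HervAnnotation:
    """A retroviral element annotated relative to its nearest gene."""

    element: GenomicInterval
    family: str
    element_type: str  # "soloLTR" or "complete"
    gene: str
    relation: str  # exonic / intronic / upstream / downstream
    distance: int  # bp gap to gene body; 0 iff exonic or intronic


class SchemaError(ValueError):
    """Raised when a required column is missing from an input table."""


_DE_COLUMNS = ("log2_fold_change", "adjusted_p")


def filter_de_cpgs(
    cpg_table: pd.DataFrame,
    genes: dict[str, CPGRecord] | None = None,
    log2fc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Keep genes that are significantly differentially expressed.

    A gene passes iff |log2 fold change| > ``log2fc_cutoff`` (strict) and
    adjusted p < ``p_cutoff`` (strict). Input order is preserved; duplicate
    gene symbols are collapsed to their first occurrence.
    """
    for col in _DE_COLUMNS + ("gene",):
        if col not in cpg_table.columns:
            raise SchemaError(f"CPG table missing required column {col!r}")
    keep = (cpg_table["log2_fold_change"].abs() > log2fc_cutoff) & (
        cpg_table["adjusted_p"] < p_cutoff
    )
    out = cpg_table.loc[keep].drop_duplicates(subset="gene", keep="first")
    return out.reset_index(drop=True)


def select_near(
    elements: list[tuple[GenomicInterval, str, str]],
    cpgs: list[CPGRecord],
    radius_bp: int = 20_000,
) -> list[HervAnnotation]:
    """Select elements within ``radius_bp`` of any gene body.

    ``elements`` are (interval, family, element_type) triples. An element is
    selected iff its gap distance to some gene body is <= radius_bp; the gap
    between [a,b) and [c,d) is max(0, c-b, a-d). Each selected element is
    annotated with its nearest gene (minimum gap; ties broken by
    lexicographically smallest symbol) and classified positionally.
    """
    if radius_bp < 0:
        raise ValueError(f"radius must be non-negative, got {radius_bp}")
    out: list[HervAnnotation] = []
    for interval, family, element_type in elements:
        best: tuple[int, str, CPGRecord] | None = None
        for gene in cpgs:
            gap = interval.gap(gene.body)
            if gap is None or gap > radius_bp:
                continue
            key = (gap, gene.symbol)
            if best is None or key < (best[0], best[1]):
                best = (gap, gene.symbol, gene)
        if best is None:
            continue
        relation, distance = classify_relation(interval, best[2])
        out.append(
            HervAnnotation(
                element=interval,
                family=family,
                element_type=element_type,
                gene=best[1],
                relation=relation,
                distance=distance,
            )
        )
    return out


def merge_regions(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals into sorted, pairwise-disjoint regions.

    Intervals are merged iff they share at least one base; bookended
    intervals ([0,10) and [10,20)) are NOT merged. Strand is dropped.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start < merged[-1].end  # strict: shared base required
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def classify_relation(
    element: GenomicInterval, gene: CPGRecord
) -> tuple[str, int]:
    """Classify an element's position relative to a gene.

    Precedence: exonic (overlaps any exon) > intronic (overlaps gene body)
    > upstream/downstream. The flank label is strand-aware: the 5' side of
    the gene is upstream, so an element past the end of a minus-strand gene
    is upstream. Returns (relation, gap distance to gene body).
    """
    gap = element.gap(gene.body)
    if gap is None:
        raise ValueError(
            f"element on {element.chrom} cannot be classified against "
            f"gene {gene.symbol} on {gene.body.chrom}"
        )
    if any(element.overlaps(exon) for exon in gene.exons):
        return "exonic", 0
    if element.overlaps(gene.body):
        return "intronic", 0
    before_gene = element.end <= gene.body.start
    if gene.body.strand == "-":
        relation = "downstream" if before_gene else "upstream"
    else:
        relation = "upstream" if before_gene else "downstream"
    return relation, gap


def summarize_annotations(annotations: list[HervAnnotation]) -> pd.DataFrame:
    """Tabulate selected elements by positional relation and element type."""
    rel = Counter(a.relation for a in annotations)
    typ = Counter(a.element_type for a in annotations)
    rows = [
        {"category": "relation", "label": k, "count": v}
        for k, v in sorted(rel.items())
    ] + [
        {"category": "element_type", "label": k, "count": v}
        for k, v in sorted(typ.items())
    ]
    return pd.DataFrame(rows, columns=["category", "label", "count"])
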