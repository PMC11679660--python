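"""Alu element substructure and poly(A)-tail variant effects.

An Alu element is a ~300 bp dimeric SINE: a left monomer and a right
monomer joined by an A-rich linker, terminated by a 3' poly(A)-tail.
Tail length matters biologically — genomic Alu tails average 21-26 bp,
while recently retrotransposition-active insertions carry much longer
tails — so single-base substitutions that fuse the tail with an adjacent
A-run (e.g. a G>A at a one-base spacer) can extend the tail by many
bases at once.

Run lengths are strict homopolymer counts of the tail base on the
element's sense strand (A for plus-strand elements, T on the reference
for minus-strand elements, handled by reverse complementing). The
measured run must contain the annotated tail anchor, so unrelated A-runs
elsewhere never count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AluElement:
    """An Alu with annotated substructure (0-based half-open, + coordinates)."""

    element: GenomicInterval
    left_monomer: GenomicInterval
    linker: GenomicInterval
    right_monomer: GenomicInterval
    tail: GenomicInterval
    family: str = "AluY"

    def __post_init__(self) -> None:
        parts = [self.left_monomer, self.linker, self.right_monomer, self.tail]
        for part in parts:
            if part.start < self.element.start or part.end > self.element.end:
                raise ValueError("substructure interval outside element")
        # 5'->3' on the sense strand: plus-strand elements run
        # left monomer, linker, right monomer, tail in ascending
        # coordinates; minus-strand elements in descending order.
        starts = [p.start for p in parts]
        if self.element.strand == "-":
            ordered = all(a >= b for a, b in zip(starts, starts[1:]))
        else:
            ordered = all(a <= b for a, b in zip(starts, starts[1:]))
        if not ordered:
            raise ValueError("substructure not ordered 5'->3' on element strand")


@dataclass
class PolyAResult:
    run_before: int
    run_after: int
    region: str  # tail / linker / left_monomer / right_monomer / outside

    @property
    def extension(self) -> int:
        return self.run_after - self.run_before


def locate_in_alu(pos: int, alu: AluElement, chrom: str | None = None) -> str:
    """Label a position by the Alu sub-region containing it."""
    if chrom is not None and chrom != alu.element.chrom:
        return "outside"
    c = alu.element.chrom
    for name, part in (
        ("tail", alu.tail),
        ("linker", alu.linker),
        ("left_monomer", alu.left_monomer),
        ("right_monomer", alu.right_monomer),
    ):
        if part.contains(c, pos):
            return name
    return "outside"


class ReferenceMismatchError(ValueError):
    pass


def _run_containing(seq: str, anchor: int, base: str) -> int:
    """Length of the maximal ``base`` homopolymer containing ``anchor``.

    Returns 0 if the anchor position itself is not ``base``.
    """
    if not (0 <= anchor < len(seq)) or seq[anchor] != base:
        return 0
    lo = anchor
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = anchor
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def polya_extension(
    sequence: str,
    alu: AluElement,
    pos: int,
    ref: str,
    alt: str,
    seq_offset: int = 0,
) -> PolyAResult:
    """Tail run length before and after applying a single-base substitution.

    ``sequence`` is the plus-strand sequence covering the element (plus
    flanks); ``seq_offset`` is the genomic coordinate of its first base,
    and ``pos`` the 0-based genomic position of the variant. The ref
    allele must match the sequence (on the plus strand); only SNVs are
    supported. For minus-strand elements the sequence is reverse
    complemented so runs are always measured on the element's sense
    strand; results are strand-invariant by construction.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-base substitutions are supported")
    i = pos - seq_offset
    if not (0 <= i < len(sequence)):
        raise ValueError("variant position outside the provided sequence")
    if sequence[i].upper() != ref.upper():
        raise ReferenceMismatchError(
            f"reference allele {ref!r} does not match sequence base "
            f"{sequence[i]!r} at position {pos}"
        )
    region = locate_in_alu(pos, alu)
    seq = sequence.upper()
    # anchor: annotated tail start on the sense strand
    if alu.element.strand == "-":
        anchor_genomic = alu.tail.end - 1
        seq = reverse_complement(seq)
        flip = lambda j: len(seq) - 1 - j
        i = flip(i)
        anchor = flip(anchor_genomic - seq_offset)
        alt_sense = reverse_complement(alt.upper())
    else:
        anchor = alu.tail.start - seq_offset
        alt_sense = alt.upper()
    before = _run_containing(seq, anchor, "A")
    edited = seq[:i] + alt_sense + seq[i + 1:]
    after = _run_containing(edited, anchor, "A")
    return PolyAResult(run_before=before, run_after=after, region=region)
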