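"""Poly(A)-tail extension by a single-base spacer substitution.

Alu elements end in a 3' poly(A) tail (21-26 bp on average in the human
genome). A substitution that turns a non-A spacer into A can fuse the
tail with a downstream A-run, extending it by many bases at once — a
change relevant to retrotransposition competence.
"""

from hervtriage.regions import GenomicInterval
from hervtriage.retroelements import AluElement, polya_extension

# tail: 29 A's, a single G, then 7 more A's
tail = "A" * 29 + "G" + "A" * 7
left, linker, right = "CGT" * 40, "AAAAA", "TGC" * 40
seq = left + linker + right + tail
tail_start = len(left) + len(linker) + len(right)

alu = AluElement(
    element=GenomicInterval("alu", 0, len(seq), "+"),
    left_monomer=GenomicInterval("alu", 0, len(left), "+"),
    linker=GenomicInterval("alu", len(left), len(left) + len(linker), "+"),
    right_monomer=GenomicInterval("alu", len(left) + len(linker), tail_start, "+"),
    tail=GenomicInterval("alu", tail_start, len(seq), "+"),
)

result = polya_extension(seq, alu, tail_start + 29, "G", "A")
print(f"variant region:   {result.region}")
print(f"run before:       {result.run_before} bp")
print(f"run after:        {result.run_after} bp")
print(f"extension:        +{result.extension} bp")
print(
    "The G>A substitution merges the 29-base tail with the 7-base run "
    "beyond the spacer, yielding a 37-base poly(A) tract."
)
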