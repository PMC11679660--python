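"""Reading and writing the pipeline's file formats.

VCF reading goes through cyvcf2; writing uses a minimal GT-only VCF v4.2
emitter (the pipeline only ever carries genotypes). Annotations travel as
BED-style TSVs, panels and metadata as plain TSV, sequences as FASTA.
Internal coordinates are 0-based half-open; VCF positions are converted
at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .ancestry import ReferencePanel
from .cohort import MISSING, GenotypeMatrix, RawSite, split_multiallelic
from .regions import CPGRecord, GenomicInterval


def read_vcf_sites(path: str | Path) -> tuple[list[str], list[RawSite]]:
    """Read a VCF into per-site allele-index genotypes (pre-splitting)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites = []
    for rec in vcf:
        pairs = np.array(
            [gt[:2] for gt in rec.genotypes], dtype=np.int16
        ) if len(samples) else np.zeros((0, 2), dtype=np.int16)
        sites.append(
            RawSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alts=list(rec.ALT),
                rsid=rec.ID or ".",
                allele_pairs=pairs,
            )
        )
    vcf.close()
    return samples, sites


def read_genotype_matrix(
    path: str | Path,
    cohort: str,
    sample_type: str,
    metadata: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a VCF, split multiallelics, and attach sample labels."""
    sample_ids, sites = read_vcf_sites(path)
    variants, genotypes = split_multiallelic(sites)
    samples = pd.DataFrame(
        {"cohort": cohort, "sample_type": sample_type},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if metadata is not None:
        samples = samples.join(
            metadata.drop(columns=["cohort", "sample_type"], errors="ignore"),
            how="left",
        )
    return GenotypeMatrix(samples=samples, variants=variants, genotypes=genotypes)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Write biallelic records with GT-only genotype columns (VCF v4.2).

    ``genotypes`` has shape (n_samples, n_variants), matching
    GenotypeMatrix.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"]
        fh.write("\t".join(header + list(sample_ids)) + "\n")
        for j, (_, v) in enumerate(variants.iterrows()):
            gts = [_GT_STRINGS[int(g)] for g in genotypes[:, j]]
            row = [
                str(v["chrom"]), str(int(v["pos"])), str(v.get("rsid", ".")),
                str(v["ref"]), str(v["alt"]), ".", "PASS", ".", "GT",
            ]
            fh.write("\t".join(row + gts) + "\n")


def write_panel(path: str | Path, panel: ReferencePanel,
                positions: pd.DataFrame | None = None) -> None:
    """Write a reference panel TSV: marker_id [chrom pos ref alt] freq_<POP>..."""
    df = panel.to_frame()
    if positions is not None:
        df = positions.merge(df, on="marker_id")
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    populations = [c[len("freq_"):] for c in freq_cols]
    return ReferencePanel(
        populations=populations,
        marker_ids=df["marker_id"].astype(str).tolist(),
        frequencies=df[freq_cols].to_numpy(dtype=float).T,
    )


def write_metadata(path: str | Path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_gene_table(path: str | Path) -> list[CPGRecord]:
    """Read gene models with DE statistics from a BED12-like TSV.

    Required columns: gene, chrom, start, end, strand, exon_starts,
    exon_ends (comma-separated absolute coordinates), log2_fold_change,
    adjusted_p.
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        body = GenomicInterval(
            str(row["chrom"]), int(row["start"]), int(row["end"]),
            str(row["strand"]),
        )
        exons = [
            GenomicInterval(body.chrom, int(s), int(e), body.strand)
            for s, e in zip(
                str(row["exon_starts"]).split(","),
                str(row["exon_ends"]).split(","),
            )
            if s != "" and s != "nan"
        ]
        records.append(
            CPGRecord(
                symbol=str(row["gene"]),
                body=body,
                exons=exons,
                log2_fold_change=float(row["log2_fold_change"]),
                adjusted_p=float(row["adjusted_p"]),
            )
        )
    return records


def gene_records_to_frame(records: list[CPGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.symbol for r in records],
            "chrom": [r.body.chrom for r in records],
            "start": [r.body.start for r in records],
            "end": [r.body.end for r in records],
            "strand": [r.body.strand for r in records],
            "exon_starts": [",".join(str(e.start) for e in r.exons) for r in records],
            "exon_ends": [",".join(str(e.end) for e in r.exons) for r in records],
            "log2_fold_change": [r.log2_fold_change for r in records],
            "adjusted_p": [r.adjusted_p for r in records],
        }
    )


def write_bed(path: str | Path, intervals: list[GenomicInterval],
              names: list[str] | None = None) -> None:
    """Write BED (3 or 6 columns) for a list of intervals."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n"
                )


def read_element_bed(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    """Read HERV/Alu elements from BED6 + family/type columns."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand",
               "family", "element_type"],
    )
    return [
        (
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            str(r.family),
            str(r.element_type),
        )
        for r in df.itertuples()
    ]


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }
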