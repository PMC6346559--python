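"""Reading and writing the pipeline's file formats.

Genomes travel as FASTA, gene models as GFF3 exon features (or 0-based
half-open BED), guide libraries and all result tables as CSV. Internal
coordinates are 1-based inclusive throughout; the BED reader converts.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment, ExonAnnotation, Genome, GuideRecord
from .snp import SNPRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3_exons",
    "write_gff3_exons",
    "read_bed_exons",
    "read_guide_library",
    "write_guide_library",
    "alignments_to_frame",
    "read_snp_table",
    "write_snp_table",
]


def read_fasta(path: str | Path) -> Genome:
    return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(genome[name]), id=name, description="") for name in genome]
    SeqIO.write(records, str(path), "fasta")


def write_gff3_exons(annotation: ExonAnnotation, path: str | Path, source: str = "screenaudit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(annotation.genes()):
            for contig, start, end in annotation.gene_intervals(gene):
                fh.write(
                    f"{contig}\t{source}\texon\t{start}\t{end}\t.\t+\t.\tgene_id={gene}\n"
                )


def read_gff3_exons(path: str | Path) -> ExonAnnotation:
    """Exon features from a GFF3 file; the gene id comes from the gene_id
    (or Parent, or ID) attribute."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    ann = ExonAnnotation()
    for feat in db.features_of_type("exon"):
        attrs = feat.attributes
        gene = (attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID") or [None])[0]
        if gene is None:
            continue
        ann.add(feat.seqid, feat.start, feat.end, gene)
    return ann


def read_bed_exons(path: str | Path) -> ExonAnnotation:
    """Exons from 0-based half-open BED (chrom, start, end, gene name)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.split()
            rows.append((f[0], int(f[1]), int(f[2]), f[3]))
    return ExonAnnotation.from_bed(rows)


def read_guide_library(path: str | Path) -> list[GuideRecord]:
    """Guide CSV with columns guide_id, spacer, intended_gene (blank = NTC)."""
    df = pd.read_csv(path, dtype=str)
    out = []
    for _, row in df.iterrows():
        gene = row.get("intended_gene")
        if pd.isna(gene) or gene == "":
            gene = None
        out.append(GuideRecord(row["guide_id"], row["spacer"], gene))
    return out


def write_guide_library(guides: Iterable[GuideRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"guide_id": g.guide_id, "spacer": g.spacer, "intended_gene": g.intended_gene or ""}
            for g in guides
        ]
    ).to_csv(path, index=False)


def alignments_to_frame(alignments: Iterable[Alignment]) -> pd.DataFrame:
    """Flat alignment table mirroring the columns of library alignment files."""
    rows = []
    for a in alignments:
        rows.append(
            {
                "guide_id": a.guide_id,
                "contig": a.contig,
                "start": a.start,
                "strand": a.strand,
                "n_mismatches": a.n_mismatches,
                "mismatch_positions": ";".join(map(str, a.mismatch_positions)),
                "substitutions": ";".join(f"{s}>{r}" for s, r in a.substitutions),
                "pam": a.pam_seq,
                "region": a.region,
                "genes": ";".join(a.genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "contig",
            "start",
            "strand",
            "n_mismatches",
            "mismatch_positions",
            "substitutions",
            "pam",
            "region",
            "genes",
        ],
    )


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """SNPs from CSV (snp_id, contig, position, ref, alt[, maf]) or minimal
    VCF (CHROM, POS, ID, REF, ALT)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        out = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                out.append(SNPRecord(f[2], f[0], int(f[1]), f[3], f[4].split(",")[0]))
        return out
    df = pd.read_csv(path)
    return [
        SNPRecord(
            str(r["snp_id"]),
            str(r["contig"]),
            int(r["position"]),
            str(r["ref"]),
            str(r["alt"]),
            float(r["maf"]) if "maf" in df.columns else float("nan"),
        )
        for _, r in df.iterrows()
    ]


def write_snp_table(snps: Iterable[SNPRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "contig": s.contig,
                "position": s.position,
                "ref": s.ref,
                "alt": s.alt,
                "maf": s.maf,
            }
            for s in snps
        ]
    ).to_csv(path, index=False)
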