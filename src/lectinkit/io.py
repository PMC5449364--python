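"""Readers and writers for the standard file formats the pipeline consumes.

FASTA goes through Biopython SeqIO, GFF3 reading through gffutils, JASPAR
PWM files through Bio.motifs; BED and the various TSV tables are plain
pandas frames. All genomic coordinates are converted to 0-based half-open
at this boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainAnnotation, GeneModel


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3

def write_gff3(models: Mapping[str, GeneModel], path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive per the standard."""
    lines = ["##gff-version 3"]
    for gene in models.values():
        g1, g2 = gene.start + 1, gene.end
        lines.append(
            f"{gene.chromosome}\tlectinkit\tgene\t{g1}\t{g2}\t.\t{gene.strand}\t.\t"
            f"ID={gene.gene_id}"
        )
        mrna = f"{gene.gene_id}.1"
        lines.append(
            f"{gene.chromosome}\tlectinkit\tmRNA\t{g1}\t{g2}\t.\t{gene.strand}\t.\t"
            f"ID={mrna};Parent={gene.gene_id}"
        )
        for s, e in gene.exons:
            lines.append(
                f"{gene.chromosome}\tlectinkit\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"Parent={mrna}"
            )
        for s, e in gene.cds:
            lines.append(
                f"{gene.chromosome}\tlectinkit\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                f"Parent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> dict[str, GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            break  # one transcript per gene in this pipeline
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        out[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            exons=tuple(sorted(exons)),
            cds=tuple(sorted(cds)),
        )
    return out


# ---------------------------------------------------------------- BED

def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into columns chrom/start/end[/name]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "name": parts[3] if len(parts) > 3 else "."})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------- PWMs (JASPAR)

def read_jaspar_pwms(path) -> list:
    """Parse a JASPAR-format PWM file into Bio.motifs Motif objects."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


def write_jaspar_pwms(motif_list, path) -> None:
    Path(path).write_text(motifs.write(motif_list, "jaspar"))


# ---------------------------------------------------------------- TSV tables

def read_domain_annotations(path) -> list[DomainAnnotation]:
    """InterProScan-style TSV: gene_id, domain accession, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(r.gene_id, r.domain_id, int(r.aa_start), int(r.aa_end))
        for r in df.itertuples()
    ]


def write_domain_annotations(annotations, path) -> None:
    pd.DataFrame(
        [(a.gene_id, a.domain_id, a.aa_start, a.aa_end) for a in annotations],
        columns=["gene_id", "domain_id", "aa_start", "aa_end"],
    ).to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def frame_to_tsv_bytes(df: pd.DataFrame) -> bytes:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue().encode()
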