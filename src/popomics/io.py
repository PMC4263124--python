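"""Shared file readers and writers (FASTA, GFF3, VCF 4.2, TSV).

All tables are tab-separated UTF-8 with '.' decimals; coordinates are
1-based inclusive in GFF3/VCF on disk and converted at these boundaries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> upper-cased sequence; duplicate ids or an empty file error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise InputError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = ["contig_id", "source", "type", "start", "end", "score",
             "strand", "phase", "attributes"]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene models from a GFF3 file.

    Returns gene_id, contig_id, start, end (1-based inclusive), strand,
    type and the raw attribute map; a feature with end < start raises with
    its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, source, ftype, start, end, score, strand, phase, attrs = fields
            start, end = int(start), int(end)
            if end < start:
                raise InputError(f"{path}:{lineno}: end {end} < start {start}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append((attr_map.get("ID", f"feature_{lineno}"), contig, start,
                         end, strand, ftype, attrs))
    if not rows:
        raise InputError(f"no features in {path}")
    df = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start", "end",
                                     "strand", "type", "attributes"])
    df["length_nt"] = df["end"] - df["start"] + 1
    return df


def write_gff3(genes: pd.DataFrame, path: str | Path,
               source: str = "popomics", ftype: str = "CDS") -> None:
    """Write gene models (gene_id, contig_id, start, end, strand) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, contig_id, start, end, strand in genes[
            ["gene_id", "contig_id", "start", "end", "strand"]
        ].itertuples(index=False):
            fh.write(f"{contig_id}\t{source}\t{ftype}\t{start}\t{end}\t.\t"
                     f"{strand}\t0\tID={gene_id}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DPG,Number=1,Type=Integer,Description="Metagenomic read depth">
##INFO=<ID=DPT,Number=1,Type=Integer,Description="Metatranscriptomic read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path,
              contigs: pd.DataFrame | None = None) -> None:
    """Write SNP records (contig, pos, ref, alt, dpg, dpt) as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs is not None:
            for contig_id, length in contigs[["contig_id", "length"]].itertuples(index=False):
                fh.write(f"##contig=<ID={contig_id},length={length}>\n")
        fh.write(_VCF_HEADER.split("\n", 1)[1])
        ordered = variants.sort_values(["contig", "pos", "ref", "alt"])
        for contig, pos, ref, alt, dpg, dpt in ordered[
            ["contig", "pos", "ref", "alt", "dpg", "dpt"]
        ].itertuples(index=False):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"DPG={int(dpg)};DPT={int(dpt)}\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with an optional '#'-prefixed metadata header line
    (units, N_i mode, index form ...)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
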