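"""File-format frontends: FASTA via Biopython, GFF3 locus annotations.

GFF3 coordinates are 1-based inclusive on disk and converted to 0-based
half-open in memory in exactly one place (here). A locus is coding when a CDS
feature shares its ``ID``/``Parent`` lineage or overlaps its gene interval.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extract import LocusAnnotation

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def _attr(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3_loci(path) -> list[LocusAnnotation]:
    """Read gene intervals (with CDS coding flags) from a GFF3 file.

    Returns one :class:`LocusAnnotation` per ``gene`` feature, 0-based
    half-open, ``is_coding`` true when a CDS names the gene (or a child mRNA)
    as ``Parent`` or overlaps the gene interval on the same sequence.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "type": str, "attributes": str},
    )
    genes: list[tuple[str, str, int, int]] = []
    gene_children: dict[str, str] = {}  # child feature ID -> gene ID
    for _, row in df[df["type"] == "gene"].iterrows():
        gid = _attr(row["attributes"], "ID") or f"gene:{row['seqid']}:{row['start']}"
        genes.append((gid, row["seqid"], int(row["start"]) - 1, int(row["end"])))
        gene_children[gid] = gid
    for _, row in df[df["type"] == "mRNA"].iterrows():
        mid = _attr(row["attributes"], "ID")
        parent = _attr(row["attributes"], "Parent")
        if mid and parent in gene_children:
            gene_children[mid] = gene_children[parent]

    coding: set[str] = set()
    cds_rows = df[df["type"] == "CDS"]
    cds_intervals: dict[str, list[tuple[int, int]]] = {}
    for _, row in cds_rows.iterrows():
        parent = _attr(row["attributes"], "Parent")
        if parent in gene_children:
            coding.add(gene_children[parent])
        cds_intervals.setdefault(str(row["seqid"]), []).append(
            (int(row["start"]) - 1, int(row["end"]))
        )

    out = []
    for gid, seqid, start, end in genes:
        is_coding = gid in coding or any(
            min(end, ce) > max(start, cs) for cs, ce in cds_intervals.get(seqid, ())
        )
        out.append(LocusAnnotation(gid, seqid, start, end, is_coding))
    return out


def write_gff3_loci(loci: Iterable[LocusAnnotation], path) -> None:
    """Write gene (+ mirroring CDS for coding loci) features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for ann in loci:
        attrs = f"ID={ann.locus_id}"
        lines.append(
            "\t".join(
                [ann.seq_id, "ssrtrace", "gene", str(ann.start + 1), str(ann.end), ".", "+", ".", attrs]
            )
        )
        if ann.is_coding:
            lines.append(
                "\t".join(
                    [
                        ann.seq_id, "ssrtrace", "CDS", str(ann.start + 1), str(ann.end),
                        ".", "+", "0", f"ID=cds-{ann.locus_id};Parent={ann.locus_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
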