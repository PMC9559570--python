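"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through Biopython; tables are TSV with a header naming the
coordinate convention (all human-facing coordinates are 1-based inclusive;
the library uses 0-based half-open internally); reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import JunctionCall, OrientationReport
from .signature import ChimeraVerdict, SignatureVerdict
from .simulate import SimRead
from .strcnv import STRLocus, format_str_notation
from .structure import CircularGenome, QuadripartiteStructure

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_reads_fastq",
    "read_fastq",
    "write_provenance_tsv",
    "structure_report_rows",
    "write_structure_tsv",
    "write_structure_json",
    "write_junction_calls_tsv",
    "orientation_report_dict",
    "write_orientation_json",
    "write_str_table_tsv",
    "write_signature_tsv",
]

COORD_NOTE = "# coordinates: 1-based inclusive"


def read_fasta(path, circular: bool = True) -> list[CircularGenome]:
    return [
        CircularGenome(rec.id, str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, genomes: Iterable[CircularGenome], wrap: int = 60) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_reads_fastq(path, reads: Sequence[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_provenance_tsv(path, reads: Sequence[SimRead]) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE + "\n")
        fh.write("read_id\tmolecule_id\torientation\thas_ir_dup\tstart\tstrand\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.molecule_id}\t{r.orientation}\t"
                f"{int(r.has_ir_dup)}\t{r.start + 1}\t{r.strand}\n"
            )


def structure_report_rows(structure: QuadripartiteStructure) -> list[dict]:
    rows = []
    for name, (s, e) in (
        ("LSC", structure.lsc), ("IR1", structure.ir1),
        ("SSC", structure.ssc), ("IR2", structure.ir2),
    ):
        rows.append(
            {
                "region": name,
                "start": s + 1,
                "end": e,
                "length": e - s,
                "ir_mismatches": structure.ir_mismatches if name.startswith("IR") else 0,
            }
        )
    return rows


def write_structure_tsv(path, structure: QuadripartiteStructure) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE + "\n")
        fh.write("region\tstart\tend\tlength\tir_mismatches\n")
        for row in structure_report_rows(structure):
            fh.write(
                f"{row['region']}\t{row['start']}\t{row['end']}\t"
                f"{row['length']}\t{row['ir_mismatches']}\n"
            )


def write_structure_json(path, structure: QuadripartiteStructure) -> None:
    payload = {
        "coordinates": "1-based inclusive",
        "regions": structure_report_rows(structure),
        "ir_len": structure.ir_len,
        "ir_mismatches": structure.ir_mismatches,
        "total_len": structure.total_len,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_junction_calls_tsv(path, calls: Iterable[JunctionCall]) -> None:
    with open(path, "w") as fh:
        fh.write("# overhangs in aligned reference bp flanking IR1\n")
        fh.write(
            "read_id\tlabel\twinning_ref\tir_coverage\tleft_overhang\tright_overhang\n"
        )
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.label}\t{c.winning_ref}\t"
                f"{c.ir_coverage:.4f}\t{c.left_overhang}\t{c.right_overhang}\n"
            )


def orientation_report_dict(report: OrientationReport) -> dict:
    return dataclasses.asdict(report)


def write_orientation_json(path, report: OrientationReport) -> None:
    Path(path).write_text(json.dumps(orientation_report_dict(report), indent=2) + "\n")


def write_str_table_tsv(path, loci: Iterable[STRLocus]) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE + "\n")
        fh.write(
            "position\tunit\tref_copies\tcopy_min\tcopy_max\tsupport\tnotation\n"
        )
        for l in loci:
            support = ",".join(f"{c}:{k}" for c, k in sorted(l.support.items()))
            notation = format_str_notation(l) if l.callable else "uncallable"
            fh.write(
                f"{l.position}\t{l.unit}\t{l.ref_copies}\t"
                f"{l.copy_min if l.callable else ''}\t"
                f"{l.copy_max if l.callable else ''}\t{support}\t{notation}\n"
            )


def write_signature_tsv(
    path, rows: Iterable[tuple[str, SignatureVerdict, ChimeraVerdict | None]]
) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE + "\n")
        fh.write(
            "assembly_id\tjunction_type\tposition\tstrand\tmismatches\t"
            "body_orientation\tis_chimeric\n"
        )
        for asm_id, sig, chim in rows:
            body = chim.body_orientation if chim else ""
            chimeric = str(chim.is_chimeric).lower() if chim else ""
            fh.write(
                f"{asm_id}\t{sig.junction_type}\t{sig.position or ''}\t"
                f"{sig.strand or ''}\t"
                f"{sig.mismatches if sig.mismatches is not None else ''}\t"
                f"{body}\t{chimeric}\n"
            )
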