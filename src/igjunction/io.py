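"""Readers and writers: FASTA/FASTQ input, AIRR Rearrangement TSV, germline tables.

The interchange format for annotated reads is the AIRR Community
Rearrangement schema as a tab-separated file (required columns plus
extension columns for the junction decomposition).  Booleans are written
T/F, missing values as empty strings.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .germline import GermlineSet, V_REGIONS
from .qc import Read

AIRR_COLUMNS = [
    "sequence_id", "sequence", "rev_comp", "productive",
    "v_call", "d_call", "j_call",
    "sequence_alignment", "germline_alignment",
    "junction", "junction_aa", "v_cigar", "d_cigar", "j_cigar",
    # extension columns
    "cdr3", "cdr3_aa", "np1", "np2", "p1", "p2", "n1", "n2",
    "v_deletion", "j_deletion", "d_deletion_5p", "d_deletion_3p",
    "v_identity", "shm_count", "ultralong",
    "v_call_ties", "ambiguous_v", "v_clan", "flags",
]


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ (gzip-transparent; format sniffed from content)."""
    handle = _open_text(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            raise ValueError(f"{path}: empty file")
        else:
            raise ValueError(f"{path}: unrecognized sequence format")
        reads = []
        seen = set()
        try:
            for rec in SeqIO.parse(handle, fmt):
                if rec.id in seen:
                    raise ValueError(f"{path}: duplicate read id {rec.id!r}")
                seen.add(rec.id)
                qual = rec.letter_annotations.get("phred_quality")
                reads.append(Read(rec.id, str(rec.seq), list(qual) if qual else None))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record after "
                             f"{len(reads)} reads: {exc}") from exc
    return reads


def write_fasta(reads: list[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.nt_sequence}\n")


def _bool(v) -> str:
    if v is None:
        return ""
    return "T" if v else "F"


def _soft_cigar(alignment, read_len: int) -> str:
    s, e = alignment.read_interval
    left = f"{s}S" if s else ""
    right = f"{read_len - e}S" if read_len - e else ""
    return left + alignment.cigar + right


def record_to_row(rec, germline_set: GermlineSet | None = None) -> dict:
    row = {c: "" for c in AIRR_COLUMNS}
    row["sequence_id"] = rec.read.read_id
    row["sequence"] = rec.read.nt_sequence
    row["rev_comp"] = "F"
    row["productive"] = _bool(rec.productive)
    row["ultralong"] = _bool(rec.ultralong)
    row["flags"] = ";".join(rec.flags)
    seq = rec.read.nt_sequence
    if rec.v_call is not None:
        aln = rec.v_call.best
        row["v_call"] = aln.gene_id
        row["v_identity"] = f"{aln.percent_identity:.6f}"
        row["shm_count"] = len(aln.mutated_positions)
        row["v_cigar"] = _soft_cigar(aln, len(seq))
        row["v_call_ties"] = ",".join(rec.v_call.ties)
        row["ambiguous_v"] = _bool(rec.v_call.ambiguous_flag)
        row["v_clan"] = rec.v_call.clan or ""
    if rec.j_call is not None:
        row["j_call"] = rec.j_call.best.gene_id
        row["j_cigar"] = _soft_cigar(rec.j_call.best, len(seq))
    if rec.d_call is not None:
        row["d_call"] = rec.d_call.best.gene_id
        row["d_cigar"] = _soft_cigar(rec.d_call.best, len(seq))
    if rec.cdr3 is not None:
        c = rec.cdr3
        row["cdr3"] = c.nt_sequence
        row["cdr3_aa"] = c.aa_sequence
        junction = seq[c.anchor_c_position : c.nt_end + 3]
        row["junction"] = junction
        if len(junction) % 3 == 0:
            from ._seq import translate
            row["junction_aa"] = translate(junction)
    if rec.v_call is not None and rec.j_call is not None:
        row["sequence_alignment"] = seq[
            rec.v_call.best.read_interval[0] : rec.j_call.best.read_interval[1]
        ]
        if germline_set is not None and rec.decomposition is not None:
            d = rec.decomposition
            vgene = germline_set[rec.v_call.best.gene_id]
            jgene = germline_set[rec.j_call.best.gene_id]
            v_tail = vgene.nt_sequence[vgene.region_bounds["FR3"][1] :]
            tail_ret = v_tail[: len(v_tail) - d.v_deletion]
            n_span = len(d.p1) + len(d.n1) + len(d.p_d5)
            n_span2 = len(d.p_d3) + len(d.n2) + len(d.p2)
            row["germline_alignment"] = (
                vgene.v_region() + tail_ret + "N" * n_span + d.retained_d
                + "N" * n_span2 + jgene.nt_sequence[d.j_deletion :]
            )
    if rec.decomposition is not None:
        d = rec.decomposition
        row["p1"], row["p2"], row["n1"], row["n2"] = d.p1, d.p2, d.n1, d.n2
        row["v_deletion"] = d.v_deletion
        row["j_deletion"] = d.j_deletion
        row["np1"] = d.p1 + d.n1 + d.p_d5
        if rec.d_call is not None and d.retained_d:
            row["d_deletion_5p"] = d.d_deletion_5p
            row["d_deletion_3p"] = d.d_deletion_3p
            row["np2"] = d.p_d3 + d.n2 + d.p2
        else:
            row["np1"] = d.p1 + d.n1 + d.n2 + d.p2
    return row


def write_airr(records, path: str | Path,
               germline_set: GermlineSet | None = None) -> None:
    """Write annotated records as an AIRR Rearrangement TSV."""
    rows = [record_to_row(rec, germline_set) for rec in records]
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_germline_fasta(germline_set: GermlineSet, fasta_path: str | Path,
                         regions_path: str | Path | None = None) -> None:
    """Write a germline set back to FASTA (+ optional region table)."""
    with open(fasta_path, "w") as fh:
        for g in sorted(germline_set.genes.values(), key=lambda x: x.gene_id):
            fh.write(f">{g.gene_id} locus={g.locus} segment={g.segment_type}\n"
                     f"{g.nt_sequence}\n")
    if regions_path is not None:
        with open(regions_path, "w") as fh:
            fh.write("gene_id\tregion\tstart\tend\n")
            for g in sorted(germline_set.genes.values(), key=lambda x: x.gene_id):
                order = ("leader",) + V_REGIONS
                for name in order:
                    if name in g.region_bounds:
                        s, e = g.region_bounds[name]
                        fh.write(f"{g.gene_id}\t{name}\t{s}\t{e}\n")


def write_rss_gff3(hits, seqid: str, path: str | Path) -> None:
    """RSS scan results as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(hits, 1):
            span = 7 + r.spacer_length + 9
            if r.strand == "+":
                start, end = r.position + 1, r.position + span
            else:
                start, end = r.position + 7 - span + 1, r.position + 7
            attrs = (f"ID=rss{i};heptamer={r.heptamer};spacer={r.spacer_length};"
                     f"nonamer={r.nonamer};mismatches={r.mismatches[0]},{r.mismatches[1]}")
            fh.write(f"{seqid}\tigjunction\trecombination_signal_sequence\t"
                     f"{start}\t{end}\t.\t{r.strand}\t.\t{attrs}\n")
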