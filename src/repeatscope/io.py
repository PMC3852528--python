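"""FASTA/FASTQ/TSV input-output.

Sequence parsing is delegated to Biopython; this module adds the
validation the pipeline contracts require (IUPAC alphabet, uppercase
normalization, line-located error messages) and the TSV writers used by
the report stages.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Contig, Read

_IUPAC = set("ACGTRYSWKMBDHVN")


class SequenceFormatError(ValueError):
    """Malformed sequence file; the message names the offending line."""


def _validate(seq: str, record_id: str, line_hint: int) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise SequenceFormatError(
            f"record {record_id!r} near line {line_hint}: "
            f"non-IUPAC characters {sorted(bad)}"
        )
    return seq


def read_sequences(path, fmt: str | None = None) -> list:
    """Load a FASTA or FASTQ file as a list of :class:`Read`.

    Ids and order are preserved; sequences are uppercased; non-IUPAC
    characters are rejected with the approximate line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    fmt = fmt.lower()
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    reads = []
    lines_per_record = 4 if fmt == "fastq" else 2
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), fmt)):
            line_hint = idx * lines_per_record + 1
            reads.append(Read(read_id=rec.id, sequence=_validate(str(rec.seq), rec.id, line_hint)))
    except ValueError as exc:  # Biopython signals structural problems this way
        if isinstance(exc, SequenceFormatError):
            raise
        line_hint = len(reads) * lines_per_record + 1
        raise SequenceFormatError(f"{path} near line {line_hint}: {exc}") from exc
    return reads


def write_fasta(path, entries) -> None:
    """Write ``(id, sequence)`` pairs (or Read/Contig objects) as FASTA."""
    records = []
    for entry in entries:
        if isinstance(entry, tuple):
            name, seq = entry
        elif isinstance(entry, Contig):
            name, seq = entry.contig_id, entry.sequence
        else:
            name, seq = entry.read_id, entry.sequence
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, reads) -> None:
    """Write reads as FASTQ with a constant dummy quality ('I')."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(read.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth_tsv(path, truth) -> None:
    """Planted-instance table: instance_id, family_id, class_label, start,
    end, kind (coordinates 0-based half-open)."""
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["instance_id", "family_id", "class_label", "start", "end", "kind"])
        for inst in truth.instances:
            writer.writerow(
                [inst.instance_id, inst.family_id, inst.class_label, inst.start, inst.end, inst.kind]
            )


def write_placements_tsv(path, placements) -> None:
    """Placement table (TSV, not SAM): read_id, ref_id, start, end, strand,
    aligned_bases, identity.

    Column mapping to SAM concepts: read_id=QNAME, ref_id=RNAME,
    start=POS (0-based here), strand=FLAG 0x10, aligned_bases=sum of
    M/I run lengths, identity=1 - NM/alignment_length.
    """
    with open(path, "w", newline="") as fh:
        fh.write("# start/end are 0-based half-open on the reference\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "ref_id", "start", "end", "strand", "aligned_bases", "identity"])
        for p in placements:
            writer.writerow(
                [p.read_id, p.ref_id, p.start, p.end, p.strand, p.aligned_bases, f"{p.identity:.4f}"]
            )


def write_table_tsv(path, header: list, rows, comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for row in rows:
            writer.writerow(list(row))


def parse_labeled_fasta(path) -> list:
    """Load a repeat library whose headers carry ``|class=<ClassLabel>``.

    Returns ``(seq_id, class_label, sequence)`` triples; an unlabeled entry
    is an error at load time.
    """
    from .core import CLASS_LABELS

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        label = None
        for token in header.split("|"):
            if token.startswith("class="):
                label = token[len("class=") :].strip()
        if label is None:
            raise SequenceFormatError(f"library entry {rec.id!r} lacks a |class= tag")
        if label not in CLASS_LABELS:
            raise SequenceFormatError(f"library entry {rec.id!r} has unknown class {label!r}")
        seq_id = header.split("|")[0].split()[0]
        out.append((seq_id, label, str(rec.seq).upper()))
    return out
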