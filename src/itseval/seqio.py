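"""Readers and writers for every file the pipeline touches.

All sequence parsing is delegated to Biopython; this module adapts its records
to the package's :class:`~itseval.core.Read` type, fixes the quality encoding
to Phred+33, and adds the small domain-specific dialects (primer tables,
``;size=N`` dereplication annotations).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

from .core import Primer, Read

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_primers",
    "write_primers",
    "write_uniques_fasta",
]

_FORMATS = ("fasta", "fastq", "fasta+qual")


def read_sequences(path: str | Path, format: str = "fasta",
                   qual_path: str | Path | None = None) -> Iterator[Read]:
    """Stream reads from FASTA, FASTQ (Phred+33) or paired FASTA+QUAL files.

    For ``fasta+qual``, ``qual_path`` defaults to ``path`` with a ``.qual``
    suffix.  A malformed record raises ``ValueError`` naming its 1-based index.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "fasta+qual":
        qual_path = Path(qual_path) if qual_path else path.with_suffix(".qual")
        with open(path) as fh, open(qual_path) as qh:
            yield from _convert(PairedFastaQualIterator(fh, qh), with_quals=True)
    else:
        with open(path) as fh:
            yield from _convert(SeqIO.parse(fh, format), with_quals=(format == "fastq"))


def _convert(records, with_quals: bool) -> Iterator[Read]:
    index = 0
    while True:
        try:
            rec = next(records)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed record {index + 1}: {exc}") from exc
        index += 1
        quals = None
        if with_quals:
            quals = list(rec.letter_annotations["phred_quality"])
        yield Read(id=rec.id, bases=str(rec.seq).upper(), quals=quals)


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.bases), id=read.id, description="")
    if read.quals is not None:
        rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def write_fasta(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTA; returns the record count."""
    return SeqIO.write((_to_record(r) for r in reads), str(path), "fasta")


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTQ (Phred+33); reads must carry qualities."""
    return SeqIO.write((_to_record(r) for r in reads), str(path), "fastq")


def read_primers(path: str | Path) -> list[Primer]:
    """Load primers from a 3/4-column TSV (name, sequence, direction[, site])
    or from FASTA (direction inferred from a trailing ``F``/``R`` in the name).
    """
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith(">"):
        primers = []
        for rec in SeqIO.parse(str(path), "fasta"):
            direction = "reverse" if rec.id.rstrip("0123456789").endswith("R") else "forward"
            primers.append(Primer(rec.id, str(rec.seq), direction))
        return primers
    primers = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, seq, direction = row[0], row[1], row[2]
            site = row[3] if len(row) > 3 else ""
            primers.append(Primer(name, seq, direction, site))
    return primers


def write_primers(primers: Sequence[Primer], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tsequence\tdirection\tbinding_site\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.sequence}\t{p.direction}\t{p.binding_site}\n")


def write_uniques_fasta(uniques, path: str | Path) -> None:
    """Write dereplicated sequences as FASTA with ``;size=N`` annotations."""
    with open(path, "w") as fh:
        for i, u in enumerate(uniques, 1):
            fh.write(f">unique{i};size={u.abundance}\n{u.sequence}\n")
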