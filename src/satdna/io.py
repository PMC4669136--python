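"""Reading and writing of sequence files (FASTA, FASTQ, EMBL flat files).

Thin wrappers over Biopython's SeqIO that normalize everything to
:class:`satdna.core.SeqRecord` (uppercase sequence, optional library label).
FASTQ qualities are parsed but not used analytically; simulated libraries are
written with a constant Q40.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from satdna.core import SeqRecord

__all__ = [
    "read_fasta",
    "read_fastq",
    "read_embl",
    "read_seqs",
    "write_fasta",
    "write_fastq",
]


def _convert(records: Iterable[BioSeqRecord], label: str | None,
             source: str | None) -> list[SeqRecord]:
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
        out.append(SeqRecord(id=r.id, seq=str(r.seq), label=label, source=source))
    return out


def read_fasta(path: str | os.PathLike, label: str | None = None) -> list[SeqRecord]:
    return _convert(SeqIO.parse(os.fspath(path), "fasta"), label, os.fspath(path))


def read_fastq(path: str | os.PathLike, label: str | None = None) -> list[SeqRecord]:
    return _convert(SeqIO.parse(os.fspath(path), "fastq"), label, os.fspath(path))


def read_embl(path: str | os.PathLike, label: str | None = None) -> list[SeqRecord]:
    """EMBL flat-file reader (sequence + ID only; features ignored)."""
    return _convert(SeqIO.parse(os.fspath(path), "embl"), label, os.fspath(path))


_READERS = {".fa": read_fasta, ".fasta": read_fasta, ".fna": read_fasta,
            ".fq": read_fastq, ".fastq": read_fastq,
            ".embl": read_embl, ".dat": read_embl}


def read_seqs(path: str | os.PathLike, label: str | None = None) -> list[SeqRecord]:
    """Read sequences, dispatching on file extension."""
    ext = os.path.splitext(os.fspath(path))[1].lower()
    reader = _READERS.get(ext)
    if reader is None:
        raise ValueError(f"unrecognized sequence file extension {ext!r}")
    return reader(path, label=label)


def write_fasta(records: Sequence[SeqRecord], path: str | os.PathLike) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, os.fspath(path), "fasta")


def write_gapped_fasta(entries: Sequence[tuple[str, str]],
                       path: str | os.PathLike) -> None:
    """Write (id, gapped sequence) pairs, e.g. MSA rows, as FASTA."""
    bio = [BioSeqRecord(Seq(seq), id=name, description="")
           for name, seq in entries]
    SeqIO.write(bio, os.fspath(path), "fasta")


def write_fastq(records: Sequence[SeqRecord], path: str | os.PathLike,
                quality: int = 40) -> None:
    """Write FASTQ with a constant per-base quality (default Q40)."""
    bio = []
    for r in records:
        b = BioSeqRecord(Seq(r.seq), id=r.id, description="")
        b.letter_annotations["phred_quality"] = [quality] * len(r.seq)
        bio.append(b)
    SeqIO.write(bio, os.fspath(path), "fastq")
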