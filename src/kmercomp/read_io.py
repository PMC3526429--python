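"""Reading and writing read sets and result artifacts.

FASTA and FASTQ (Sanger qualities), optionally gzip-compressed, parsed with
Biopython.  Results are written as read-subset files in the source format, a
TSV similarity matrix, and a Newick dendrogram.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = ["Read", "ReadSet", "read_sequences", "write_subset", "write_matrix", "write_newick"]

_FASTA_WRAP = 80


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None  # Sanger-encoded, FASTQ only


@dataclass
class ReadSet:
    """An ordered collection of named DNA reads from one sample."""

    sample_name: str
    reads: list[Read] = field(default_factory=list)
    source_format: str = "fasta"  # "fasta" | "fastq"

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot detect format (first byte {first!r})")


def _sample_name_from_path(path: Path) -> str:
    """File name minus .gz and one sequence-format extension; inner dots
    are kept so 'run1.A.fasta' and 'run1.B.fasta' stay distinct."""
    name = path.name
    if name.lower().endswith(".gz"):
        name = name[:-3]
    for ext in (".fasta", ".fa", ".fna", ".fastq", ".fq"):
        if name.lower().endswith(ext):
            name = name[: -len(ext)]
            break
    return name


def read_sequences(path, format_hint: str | None = None, sample_name: str | None = None) -> ReadSet:
    """Load a FASTA/FASTQ file (gzip ok) into a :class:`ReadSet`.

    Sequences are uppercased; read order is preserved.  Duplicate read ids
    are disambiguated with an appended ``.<ordinal>`` and a logged warning.
    """
    path = Path(path)
    fmt = (format_hint or _sniff_format(path)).lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    name = sample_name or _sample_name_from_path(path)
    reads: list[Read] = []
    seen: dict[str, int] = {}
    with _open_maybe_gzip(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {rec.id!r} (#{i + 1}) has an empty sequence")
            rid = rec.id
            if rid in seen:
                seen[rid] += 1
                new_id = f"{rid}.{seen[rid]}"
                logger.warning("%s: duplicate read id %r renamed to %r", path, rid, new_id)
                rid = new_id
            else:
                seen[rid] = 0
            qual = None
            if fmt == "fastq":
                phred = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(q + 33) for q in phred)
            reads.append(Read(rid, seq, qual))
    return ReadSet(sample_name=name, reads=reads, source_format=fmt)


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
    if read.quality is not None:
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in read.quality]
    return rec


def write_subset(readset: ReadSet, member_flags, path) -> None:
    """Write the flagged reads, in original order, in the source format."""
    flags = np.asarray(member_flags, dtype=bool)
    if flags.shape != (len(readset),):
        raise ValueError(
            f"flag vector length {flags.size} != read count {len(readset)}"
        )
    path = Path(path)
    fmt = readset.source_format
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        if fmt == "fasta":
            for read, keep in zip(readset.reads, flags):
                if not keep:
                    continue
                fh.write(f">{read.id}\n")
                for start in range(0, len(read.sequence), _FASTA_WRAP):
                    fh.write(read.sequence[start : start + _FASTA_WRAP] + "\n")
        else:
            records = (r for r, keep in zip(readset.reads, flags) if keep)
            SeqIO.write((_to_record(r) for r in records), fh, "fastq")


def write_matrix(names, similarity, path) -> None:
    """Write a square similarity matrix as TSV with 2-decimal cells."""
    import pandas as pd

    mat = np.asarray(similarity, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] != len(names):
        raise ValueError(f"matrix shape {mat.shape} does not match {len(names)} names")
    df = pd.DataFrame(mat, index=list(names), columns=list(names))
    df.to_csv(path, sep="\t", float_format="%.2f", index_label="sample")


def read_matrix(path):
    """Inverse of :func:`write_matrix`; returns (names, matrix)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def write_newick(tree, path) -> None:
    """Write a dendrogram (an ``skbio.TreeNode``) as Newick with branch
    lengths."""
    tree.write(str(path), format="newick")
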