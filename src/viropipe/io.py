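"""Strict readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; this layer enforces the
pipeline's invariants (unique ids, non-empty sequences, a single canonical
alphabet) and refuses to repair malformed input silently. All coordinates
elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, nucleotide or protein, validated on construction."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """A mate pair with per-base qualities; mates must match their qualities."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(f"read pair {self.id!r}: sequence/quality length mismatch")


def _canonicalize(seq: str, alphabet: frozenset, where: str) -> str:
    out = seq.upper().replace("U", "T") if alphabet is NUCLEOTIDE_ALPHABET else seq.upper()
    bad = set(out) - alphabet
    if bad:
        pos = next(i for i, c in enumerate(out) if c in bad)
        raise FormatError(f"{where}: invalid character {out[pos]!r} at position {pos}")
    return out


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated records, order preserved.

    Parameters
    ----------
    alphabet : "nucleotide" or "protein"
        Controls the permitted character set. Nucleotide sequences are
        uppercased and U is mapped to T.
    """
    alpha = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = _canonicalize(str(rec.seq), alpha, f"{path}:{rec.id}")
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for idx in range(0, len(lines), 4):
        head, seq, plus, qual = lines[idx : idx + 4]
        recno = idx // 4
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed 4-line block at record {recno}")
        if len(seq) != len(qual) or not seq:
            raise FormatError(f"{path}: malformed record {recno}: sequence/quality length mismatch")
        out.append((head[1:].split()[0], seq, qual))
    return out


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read synchronized paired FASTQ files; pairs are matched by order."""
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise FormatError(
            f"mate-count mismatch: {path1} has {len(r1)} records, {path2} has {len(r2)}"
        )
    pairs = []
    for (id1, s1, q1), (_id2, s2, q2) in zip(r1, r2):
        s1 = _canonicalize(s1, NUCLEOTIDE_ALPHABET, f"{path1}:{id1}")
        s2 = _canonicalize(s2, NUCLEOTIDE_ALPHABET, f"{path2}:{id1}")
        pairs.append(ReadPair(id=id1, seq1=s1, seq2=s2, qual1=q1, qual2=q2))
    return pairs


def write_fastq_pairs(pairs: Sequence[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_tsv_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labeled numeric matrix as TSV; labels must be unique."""
    if matrix.size == 0:
        raise FormatError("refusing to write an empty matrix")
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise FormatError("matrix labels must be unique")
    matrix.to_csv(path, sep="\t", index_label="id")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(tree, path) -> None:
    """Write a sample cluster tree as Newick; AU/BP stored as node comments."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
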