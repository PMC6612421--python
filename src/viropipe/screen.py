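"""Contig pre-processing: circularity detection, ORF calling, contaminant removal.

Circularity is called from a direct terminal repeat (DTR): an exact prefix
of the contig repeated as its suffix, the standard assembly signature of a
circular genome. The redundant copy is trimmed. The ORF caller is a
deterministic six-frame stop-to-stop scanner reporting from the first ATG.
Contaminant screening reuses the chained ANI engine with the aligned
fraction measured on the screened contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .align import SubjectIndex, chain_identity
from ._kernels import encode_nt
from .io import SequenceRecord

DEFAULT_MIN_REPEAT = 20
DEFAULT_MIN_ORF_AA = 30


@dataclass(frozen=True)
class ContigRecord:
    """A contig with circularity state and an external viral-category annotation.

    viral_category carries the upstream classifier's confidence tier
    (1 = most confident, 2 = likely, 3 = possible, None = not called);
    it is consumed, never computed, here.
    """

    id: str
    seq: str
    circular: bool = False
    terminal_repeat_len: int = 0
    viral_category: int | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein; start/end are 0-based half-open contig coordinates.

    For circular contigs the coordinates refer to the trimmed (linearized)
    sequence; an origin-spanning ORF has end > contig length, wrapping
    implied. Frames are +1/+2/+3 on the given strand, negative for the
    reverse complement.
    """

    id: str
    contig_id: str
    frame: int
    start: int
    end: int
    seq: str


def detect_circularity(
    record: SequenceRecord, min_repeat: int = DEFAULT_MIN_REPEAT, viral_category: int | None = None
) -> ContigRecord:
    """Detect a direct terminal repeat and trim the redundant 3' copy.

    The contig is circular iff its longest exact prefix that equals a
    suffix has length >= min_repeat (capped at half the contig). Raises
    ValueError for contigs of length <= 2 * min_repeat.
    """
    seq = record.seq
    n = len(seq)
    if n < 2 * min_repeat:
        raise ValueError(
            f"contig {record.id}: length {n} too short for circularity detection "
            f"(need >= {2 * min_repeat})"
        )
    probe = seq[:min_repeat]
    best_k = 0
    p = seq.find(probe, n - n // 2)  # smallest p with k <= n//2 => longest repeat
    while p != -1:
        k = n - p
        if k >= min_repeat and seq[:k] == seq[p:]:
            best_k = k
            break
        p = seq.find(probe, p + 1)
    if best_k:
        return ContigRecord(
            id=record.id,
            seq=seq[: n - best_k],
            circular=True,
            terminal_repeat_len=best_k,
            viral_category=viral_category,
        )
    return ContigRecord(id=record.id, seq=seq, circular=False, viral_category=viral_category)


def _orfs_one_strand(seq: str, strand: int, contig_len: int, min_orf_aa: int, scan_circular: bool):
    """Yield (frame, start_nt, end_nt, protein) in scan-sequence coordinates."""
    n = len(seq)
    for off in range(3):
        ncod = (n - off) // 3
        aa = str(Seq(seq[off : off + 3 * ncod]).translate())
        # stop-to-stop segments, including the open ends
        seg_start = 0
        for i, ch in enumerate(aa + "*"):
            if ch != "*":
                continue
            seg = aa[seg_start:i]
            m = seg.find("M")
            if m >= 0:
                orf = seg[m:]
                has_stop = i < len(aa)
                if len(orf) >= min_orf_aa and len(orf) <= (contig_len // 3):
                    a0 = seg_start + m
                    start_nt = off + 3 * a0
                    end_nt = off + 3 * (i + (1 if has_stop else 0))
                    yield off + 1 if strand > 0 else -(off + 1), start_nt, end_nt, orf
            seg_start = i + 1


def call_orfs(contig: ContigRecord, min_orf_aa: int = DEFAULT_MIN_ORF_AA) -> list[ProteinRecord]:
    """Six-frame stop-to-stop ORFs reported from the first ATG.

    Circular contigs are scanned on their doubled sequence so ORFs spanning
    the origin are recovered; each ORF is reported once, anchored at its
    start position modulo the contig length.
    """
    L = contig.length
    scan = contig.seq + contig.seq if contig.circular else contig.seq
    out: list[ProteinRecord] = []
    seen: set[tuple[int, int]] = set()
    for strand, strand_seq in ((1, scan), (-1, str(Seq(scan).reverse_complement()))):
        for frame, s_nt, e_nt, orf in _orfs_one_strand(
            strand_seq, strand, L, min_orf_aa, contig.circular
        ):
            if strand > 0:
                start, end = s_nt, e_nt
            else:
                start, end = len(scan) - e_nt, len(scan) - s_nt
            if contig.circular:
                shift = (start // L) * L
                start -= shift
                end -= shift
                if start >= L:
                    continue
            key = (strand * (abs(frame)), start % L if contig.circular else start)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ProteinRecord(
                    id=f"{contig.id}|orf{len(out)}",
                    contig_id=contig.id,
                    frame=frame,
                    start=start,
                    end=end,
                    seq=orf,
                )
            )
    out.sort(key=lambda p: (p.start, p.frame))
    return [
        ProteinRecord(
            id=f"{p.contig_id}|orf{i}",
            contig_id=p.contig_id,
            frame=p.frame,
            start=p.start,
            end=p.end,
            seq=p.seq,
        )
        for i, p in enumerate(out)
    ]


def screen_contaminants(
    contigs: list[ContigRecord],
    contaminant_db: list[SequenceRecord],
    min_ani: float = 95.0,
    min_af: float = 80.0,
) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Remove contigs matching a lab contaminant at >min_ani ANI over >=min_af
    percent of the contig.

    The aligned fraction is measured on the screened contig (not the
    contaminant). Returns (kept contigs, removal report) where the report
    has columns contig_id, contaminant_id, ani, af.
    """
    if not contaminant_db:
        raise ValueError("contaminant database is empty")
    indexes = [(db.id, SubjectIndex(db.seq)) for db in contaminant_db]
    kept: list[ContigRecord] = []
    rows = []
    for contig in contigs:
        q = encode_nt(contig.seq)
        hit = None
        for db_id, idx in indexes:
            ani, af, _, _ = chain_identity(q, idx)
            if ani > min_ani and af >= min_af:
                if hit is None or ani * af > hit[1] * hit[2]:
                    hit = (db_id, ani, af)
        if hit is None:
            kept.append(contig)
        else:
            rows.append(
                {"contig_id": contig.id, "contaminant_id": hit[0], "ani": hit[1], "af": hit[2]}
            )
    report = pd.DataFrame(rows, columns=["contig_id", "contaminant_id", "ani", "af"])
    return kept, report
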