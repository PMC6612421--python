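"""Nucleotide ANI / aligned-fraction computation.

Two routes are provided:

* :func:`ani_aligned_fraction` — the production engine. Exact 15-mer
  anchors shared by the two sequences are grouped by diagonal, each
  diagonal is extended gaplessly with an X-drop criterion, and the
  resulting blocks are chained greedily (non-overlapping on the query).
  ANI is matches over aligned columns across all blocks; AF is the
  fraction of the shorter sequence covered by blocks. Indels between
  homologous blocks surface as distinct diagonals.
* :func:`ani_exhaustive` — a full Smith-Waterman affine-gap alignment
  (single best local alignment, both strands). O(nm); use on small
  instances as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import (
    build_kmer_index,
    encode_nt,
    extend_gapless,
    kmer_values,
    local_affine_dp,
    revcomp_codes,
)

MIN_ANI_LEN = 100
DEFAULT_K = 15
_XDROP = 30
_MATCH = 1
_MISMATCH = -3


@dataclass(frozen=True)
class AniResult:
    """Pairwise average nucleotide identity and aligned fraction (percent)."""

    query_id: str
    subject_id: str
    ani: float
    af: float


class SubjectIndex:
    """Reusable sorted k-mer index over one subject sequence."""

    def __init__(self, seq: str, k: int = DEFAULT_K):
        self.k = k
        self.codes = encode_nt(seq)
        self.sk, self.sp = build_kmer_index(self.codes, k)


def _blocks_for_strand(q: np.ndarray, idx: SubjectIndex) -> tuple[int, int, int]:
    """(matches, columns, query_cov) over chained gapless blocks, one strand."""
    k = idx.k
    if q.shape[0] < k or idx.sp.shape[0] == 0:
        return 0, 0, 0
    qvals, qvalid = kmer_values(q, k)
    qpos_all = np.nonzero(qvalid)[0]
    qv = qvals[qpos_all]
    lo = np.searchsorted(idx.sk, qv)
    hi = np.searchsorted(idx.sk, qv + 1)
    counts = hi - lo
    nhits = int(counts.sum())
    if nhits == 0:
        return 0, 0, 0
    qpos = np.repeat(qpos_all, counts).astype(np.int64)
    spos = np.empty(nhits, dtype=np.int64)
    w = 0
    for i in range(qpos_all.shape[0]):
        c = counts[i]
        if c:
            spos[w : w + c] = idx.sp[lo[i] : hi[i]]
            w += c
    diag = spos - qpos
    order = np.argsort(diag, kind="stable")
    diag = diag[order]
    qpos = qpos[order]
    boundaries = np.nonzero(np.diff(diag))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [diag.shape[0]]))
    blocks = []
    for s, e in zip(starts, ends):
        d = int(diag[s])
        q0 = int(qpos[s:e].min())
        q1 = int(qpos[s:e].max()) + k
        q0, q1, matches = extend_gapless(q, idx.codes, q0, q1, d, _MATCH, _MISMATCH, _XDROP)
        blocks.append((matches, q0, q1))
    blocks.sort(key=lambda b: (-b[0], b[1]))
    accepted: list[tuple[int, int]] = []
    tot_matches = 0
    tot_cols = 0
    for matches, q0, q1 in blocks:
        length = q1 - q0
        if length <= 0:
            continue
        overlap = 0
        for a0, a1 in accepted:
            overlap += max(0, min(q1, a1) - max(q0, a0))
        if overlap > 0.2 * length:
            continue
        accepted.append((q0, q1))
        tot_matches += matches
        tot_cols += length
    # query coverage = union of accepted intervals
    accepted.sort()
    cov = 0
    cur0, cur1 = -1, -1
    for a0, a1 in accepted:
        if a0 > cur1:
            cov += cur1 - cur0 if cur1 > cur0 else 0
            cur0, cur1 = a0, a1
        else:
            cur1 = max(cur1, a1)
    if cur1 > cur0:
        cov += cur1 - cur0
    return tot_matches, tot_cols, cov


def chain_identity(
    q_codes: np.ndarray, idx: SubjectIndex
) -> tuple[float, float, int, int]:
    """Best-strand chained alignment of query against an indexed subject.

    Returns (ani, af_query, matches, columns) with AF relative to the query.
    """
    best = (0.0, 0.0, 0, 0)
    best_key = -1.0
    for strand_q in (q_codes, revcomp_codes(q_codes)):
        matches, cols, cov = _blocks_for_strand(strand_q, idx)
        if cols == 0:
            continue
        ani = 100.0 * matches / cols
        af = 100.0 * cov / q_codes.shape[0]
        key = ani * af
        if key > best_key:
            best_key = key
            best = (ani, af, matches, cols)
    return best


def ani_aligned_fraction(a, b) -> AniResult:
    """ANI and aligned fraction between two sequence records.

    AF is computed on the shorter sequence, making the result symmetric
    under argument swap. Raises ValueError for sequences under 100 nt.
    """
    if len(a.seq) < MIN_ANI_LEN or len(b.seq) < MIN_ANI_LEN:
        raise ValueError(
            f"ANI requires sequences >= {MIN_ANI_LEN} nt ({a.id}: {len(a.seq)}, {b.id}: {len(b.seq)})"
        )
    if len(a.seq) <= len(b.seq):
        q, s = a, b
    else:
        q, s = b, a
    idx = SubjectIndex(s.seq)
    ani, af, _, _ = chain_identity(encode_nt(q.seq), idx)
    return AniResult(query_id=a.id, subject_id=b.id, ani=ani, af=af)


def ani_exhaustive(a, b, gap_open: int = 5, gap_ext: int = 2) -> AniResult:
    """Full-DP reference ANI: single best local alignment on either strand."""
    if len(a.seq) < MIN_ANI_LEN or len(b.seq) < MIN_ANI_LEN:
        raise ValueError("ANI requires sequences >= 100 nt")
    qrec, srec = (a, b) if len(a.seq) <= len(b.seq) else (b, a)
    q = encode_nt(qrec.seq)
    s = encode_nt(srec.seq)
    best = None
    best_key = -1.0
    for qs in (q, revcomp_codes(q)):
        score, matches, cols, q0, q1, _, _ = local_affine_dp(
            qs, s, 2, -3, gap_open, gap_ext
        )
        if cols == 0:
            continue
        ani = 100.0 * matches / cols
        qcols = q1 - q0
        af = 100.0 * qcols / q.shape[0]
        key = ani * af
        if key > best_key:
            best_key = key
            best = (ani, af)
    if best is None:
        best = (0.0, 0.0)
    return AniResult(query_id=a.id, subject_id=b.id, ani=best[0], af=best[1])
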