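"""Numba dynamic-programming kernels shared by the alignment-heavy stages.

Everything here works on uint8-encoded sequences (A=0, C=1, G=2, T=3, N=4;
amino acids 0..19, X/other=20). Scores are integers for nucleotide kernels
and float32 half-bits for profile kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = np.full(256, 20, dtype=np.uint8)
for _i, _c in enumerate(AA_ORDER):
    _AA_CODE[ord(_c)] = _i

NEG_INF = np.int32(-(10**9) // 2)


def encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
    return out[::-1].copy()


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer into an int64; k-mers containing non-ACGT are invalid."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        vals = vals * 4 + np.where(c[j : n - k + 1 + j] < 4, c[j : n - k + 1 + j], 0)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[: n - k + 1]) == 0
    return vals, valid


def build_kmer_index(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (kmer, position) index over an encoded sequence."""
    vals, valid = kmer_values(codes, k)
    pos = np.nonzero(valid)[0].astype(np.int64)
    vals = vals[pos]
    order = np.argsort(vals, kind="stable")
    return vals[order], pos[order]


@njit(cache=True)
def local_affine_dp(a, b, match, mismatch, gap_open, gap_ext):
    """Exhaustive Smith-Waterman with affine gaps and full traceback.

    Returns (score, matches, columns, a0, a1, b0, b1) for the single best
    local alignment; coordinates 0-based half-open. Intended as the
    reference aligner for cross-checks; O(len(a)*len(b)) time and memory.
    """
    n = a.shape[0]
    m = b.shape[0]
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    hprev = np.zeros(m + 1, np.int32)
    hcur = np.zeros(m + 1, np.int32)
    fcol = np.full(m + 1, NEG_INF, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        hcur[0] = 0
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = hcur[j - 1] - gap_open
            e_ext = e - gap_ext
            if e_open >= e_ext:
                e = e_open
                eb = np.uint8(4)
            else:
                e = e_ext
                eb = np.uint8(0)
            f_open = hprev[j] - gap_open
            f_ext = fcol[j] - gap_ext
            if f_open >= f_ext:
                fcol[j] = f_open
                fb = np.uint8(8)
            else:
                fcol[j] = f_ext
                fb = np.uint8(0)
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            diag = hprev[j - 1] + s
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if fcol[j] > h:
                h = fcol[j]
                p = np.uint8(2)
            if e > h:
                h = e
                p = np.uint8(3)
            hcur[j] = h
            ptr[i, j] = p | eb | fb
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = hprev
        hprev = hcur
        hcur = tmp
    # traceback
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0  # 0=H, 1=F(up), 2=E(left)
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            d = p & 3
            if d == 0:
                break
            if d == 1:
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif d == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            opened = p & 8
            i -= 1
            if opened:
                state = 0
        else:
            cols += 1
            opened = p & 4
            j -= 1
            if opened:
                state = 0
    return best, matches, cols, i, bi, j, bj


@njit(cache=True)
def extend_gapless(q, s, q0, q1, diag, match, mismatch, xdrop):
    """X-drop gapless extension of a seed range along one diagonal.

    q[i] is compared with s[i+diag]. Returns (new_q0, new_q1, matches)
    over the extended range.
    """
    nq = q.shape[0]
    ns = s.shape[0]
    # extend right
    score = 0
    bestscore = 0
    bestq1 = q1
    i = q1
    while i < nq and i + diag < ns:
        if q[i] == s[i + diag] and q[i] < 4:
            score += match
        else:
            score += mismatch
        i += 1
        if score > bestscore:
            bestscore = score
            bestq1 = i
        elif bestscore - score > xdrop:
            break
    q1 = bestq1
    # extend left
    score = 0
    bestscore = 0
    bestq0 = q0
    i = q0 - 1
    while i >= 0 and i + diag >= 0:
        if q[i] == s[i + diag] and q[i] < 4:
            score += match
        else:
            score += mismatch
        if score > bestscore:
            bestscore = score
            bestq0 = i
        elif bestscore - score > xdrop:
            break
        i -= 1
    q0 = bestq0
    matches = 0
    for i in range(q0, q1):
        if q[i] == s[i + diag] and q[i] < 4:
            matches += 1
    return q0, q1, matches


@njit(cache=True)
def profile_local_dp(pssm, p, gap_open, gap_ext):
    """Best local profile-to-sequence alignment with affine gaps.

    pssm: (ncols, 21) float32 scores; p: encoded protein. Returns
    (score, seq_start, seq_end), 0-based half-open on the protein.
    """
    n = pssm.shape[0]
    m = p.shape[0]
    neg = np.float32(-1e30)
    hprev = np.zeros(m + 1, np.float32)
    hcur = np.zeros(m + 1, np.float32)
    hsprev = np.zeros(m + 1, np.int32)
    hscur = np.zeros(m + 1, np.int32)
    fcol = np.full(m + 1, neg, np.float32)
    fstart = np.zeros(m + 1, np.int32)
    best = np.float32(0.0)
    b0 = 0
    b1 = 0
    for j in range(m + 1):
        hsprev[j] = j
    for i in range(1, n + 1):
        hcur[0] = 0.0
        hscur[0] = 0
        e = neg
        estart = 0
        for j in range(1, m + 1):
            e_open = hcur[j - 1] - gap_open
            e_ext = e - gap_ext
            if e_open >= e_ext:
                e = e_open
                estart = hscur[j - 1]
            else:
                e = e_ext
            f_open = hprev[j] - gap_open
            f_ext = fcol[j] - gap_ext
            if f_open >= f_ext:
                fcol[j] = f_open
                fstart[j] = hsprev[j]
            else:
                fcol[j] = f_ext
            diag = hprev[j - 1] + pssm[i - 1, p[j - 1]]
            h = np.float32(0.0)
            hs = j
            if diag > h:
                h = diag
                hs = hsprev[j - 1]
            if fcol[j] > h:
                h = fcol[j]
                hs = fstart[j]
            if e > h:
                h = e
                hs = estart
            hcur[j] = h
            hscur[j] = hs
            if h > best:
                best = h
                b0 = hs
                b1 = j
        tmp = hprev
        hprev = hcur
        hcur = tmp
        tmps = hsprev
        hsprev = hscur
        hscur = tmps
    return best, b0, b1


@njit(cache=True)
def banded_edit_distance(a, b, band):
    """Global edit distance between a and b restricted to |i-j| <= band."""
    n = a.shape[0]
    m = b.shape[0]
    if abs(n - m) > band:
        return n + m
    big = n + m + 1
    width = 2 * band + 1
    prev = np.full(width, big, np.int32)
    cur = np.full(width, big, np.int32)
    # row 0: D[0][j] = j for j <= band
    for j in range(0, min(m, band) + 1):
        prev[j - 0 + band] = j
    for i in range(1, n + 1):
        for x in range(width):
            cur[x] = big
        jlo = max(0, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            x = j - i + band
            v = big
            if j > 0:
                sub = prev[x] if 0 <= x < width else big  # prev row, j-1 -> x = (j-1)-(i-1)+band = x
                if sub < big:
                    cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1
                    v = sub + cost
            if x + 1 < width and prev[x + 1] < big:  # deletion from a: (i-1, j)
                if prev[x + 1] + 1 < v:
                    v = prev[x + 1] + 1
            if j > 0 and x - 1 >= 0 and cur[x - 1] < big:  # insertion: (i, j-1)
                if cur[x - 1] + 1 < v:
                    v = cur[x - 1] + 1
            if j == 0:
                v = i
            cur[x] = v
        tmp = prev
        prev = cur
        cur = tmp
    x = m - n + band
    return prev[x]


@njit(cache=True)
def _read_best_placement(read, refcat, sk, sp, k, step, max_cand, cand, scratch):
    """Best gapless placement of one read orientation; returns (start, matches)."""
    L = read.shape[0]
    ncand = 0
    for off in range(0, L - k + 1, step):
        val = np.int64(0)
        ok = True
        for j in range(k):
            c = read[off + j]
            if c >= 4:
                ok = False
                break
            val = val * 4 + c
        if not ok:
            continue
        lo = np.searchsorted(sk, val)
        hi = np.searchsorted(sk, val + 1)
        for t in range(lo, hi):
            start = sp[t] - off
            if start < 0 or start + L > refcat.shape[0]:
                continue
            dup = False
            for c2 in range(ncand):
                if cand[c2] == start:
                    dup = True
                    break
            if not dup and ncand < max_cand:
                cand[ncand] = start
                ncand += 1
    best_m = -1
    best_start = np.int64(-1)
    for c2 in range(ncand):
        start = cand[c2]
        mcount = 0
        valid = True
        for j in range(L):
            r = refcat[start + j]
            if r >= 4:
                valid = False
                break
            if r == read[j]:
                mcount += 1
        if not valid:
            continue
        if mcount > best_m or (mcount == best_m and start < best_start):
            best_m = mcount
            best_start = start
    return best_start, best_m


@njit(cache=True)
def recruit_reads(reads, refcat, sk, sp, k, step, min_identity, band, depth):
    """Map every read to its best placement over the concatenated references.

    reads: (n, L) uint8, forward orientation as sequenced. Placement search
    is gapless on exact k-mer seeds every `step` positions on both strands;
    a banded edit-distance refinement rescues placements whose gapless
    identity falls in [70, min_identity). depth is incremented in place
    over concatenated-reference coordinates.

    Returns (start, identity, strand) arrays; start = -1 for unmapped.
    """
    n = reads.shape[0]
    L = reads.shape[1]
    max_cand = 256
    cand = np.empty(max_cand, np.int64)
    scratch = np.empty(0, np.int64)
    out_start = np.full(n, -1, np.int64)
    out_ident = np.zeros(n, np.float32)
    out_strand = np.zeros(n, np.int8)
    rc = np.empty(L, np.uint8)
    for r in range(n):
        fwd = reads[r]
        for j in range(L):
            c = fwd[L - 1 - j]
            rc[j] = 3 - c if c < 4 else 4
        s_f, m_f = _read_best_placement(fwd, refcat, sk, sp, k, step, max_cand, cand, scratch)
        s_r, m_r = _read_best_placement(rc, refcat, sk, sp, k, step, max_cand, cand, scratch)
        if m_f >= m_r:
            start = s_f
            matches = m_f
            strand = np.int8(1)
        else:
            start = s_r
            matches = m_r
            strand = np.int8(-1)
        if start < 0:
            continue
        ident = np.float32(100.0) * matches / L
        if ident < min_identity and ident >= 70.0:
            oriented = fwd if strand == 1 else rc
            dist = banded_edit_distance(refcat[start : start + L], oriented, band)
            ident2 = np.float32(100.0) * (L - dist) / L
            if ident2 > ident:
                ident = ident2
        if ident >= min_identity:
            out_start[r] = start
            out_ident[r] = ident
            out_strand[r] = strand
            for j in range(L):
                depth[start + j] += 1
    return out_start, out_ident, out_strand
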