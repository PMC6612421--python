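"""Profile-based ssDNA marker gene detection.

The marker model is a gapped position-specific scoring matrix (PSSM) in
half-bit log-odds units with affine gap penalties, searched by local
profile-to-sequence alignment. Statistical significance comes from an
explicit decoy calibration: scores of random background-composition
sequences are fitted to a Gumbel distribution by maximum likelihood, and
E-values are computed from the fitted survival function. The score scale
is therefore not comparable to HMMER bit scores even though the same
nominal cutoffs (score >= 50 half-bits, E <= 0.001) are used as defaults;
the calibrated E-value cutoff is the operative filter.

The two-step procedure mirrors marker bootstrapping on real viromes:
seed profiles are searched against proteins of circular contigs only
(step 1, presumed complete ssDNA genomes); a new profile is then built
from each marker's step-1 hit proteins and searched against all proteins
(step 2), recovering diverged or fragmented relatives.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from ._kernels import AA_ORDER, encode_aa, profile_local_dp
from .io import read_fasta
from .screen import ContigRecord, ProteinRecord

# Robinson-Robinson amino-acid background frequencies, alphabetical order.
BACKGROUND = np.array(
    [0.0787, 0.0192, 0.0535, 0.0629, 0.0386, 0.0738, 0.0219, 0.0514, 0.0598, 0.0901,
     0.0224, 0.0448, 0.0520, 0.0426, 0.0512, 0.0711, 0.0585, 0.0644, 0.0128, 0.0321]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MAX_EVALUE = 1e-3
GAP_OPEN = 10.0
GAP_EXT = 1.0
PSEUDOCOUNT = 0.5
MAX_GAP_FRACTION = 0.5

#: marker profile name prefix -> ssDNA class it diagnoses
MARKER_CLASS = {"viral_rep_like": "CRESS", "phage_f_like": "Microviridae"}
MICRO_WINDOW = (4000, 8000)
CRESS_WINDOW = (1000, 5000)


@dataclass(frozen=True)
class MarkerProfile:
    """A position-specific scoring model over the 20 amino acids.

    matrix is (ncols, 21) float32 half-bit log-odds; column 20 scores X
    (and any unknown residue) as 0. calibration holds the Gumbel
    (location, scale) fitted from decoy scores, None until calibrated.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray
    calibration: tuple[float, float] | None = None

    @property
    def ncols(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        # decode the most probable residue per column: argmax of the implied
        # frequency bg * 2^(score/2), not of the log-odds (which would favor
        # rare-background residues)
        freq = self.background * np.exp2(self.matrix[:, :20] / 2.0)
        return "".join(AA_ORDER[i] for i in freq.argmax(axis=1))


@dataclass(frozen=True)
class MarkerHit:
    protein_id: str
    contig_id: str
    profile_name: str
    score: float
    evalue: float
    align_start: int
    align_end: int


@dataclass(frozen=True)
class SsdnaCall:
    """A per-contig ssDNA classification with its best supporting hit."""

    contig_id: str
    call_class: str  # Microviridae | CRESS | flagged-only
    supporting_hit: MarkerHit


def profile_from_alignment(name: str, rows: list[str]) -> MarkerProfile:
    """Build a PSSM from pre-aligned (equal-length, '-'-gapped) sequences."""
    if not rows:
        raise ValueError("cannot build a profile from zero sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"profile {name}: aligned rows differ in length")
    n = len(rows)
    counts = np.zeros((width, 20), dtype=np.float64)
    gaps = np.zeros(width, dtype=np.int64)
    codes = [encode_aa(r.replace("-", "X").upper()) for r in rows]
    for r, row in enumerate(rows):
        cd = codes[r]
        for j in range(width):
            if row[j] == "-":
                gaps[j] += 1
            elif cd[j] < 20:
                counts[j, cd[j]] += 1
    keep = gaps <= MAX_GAP_FRACTION * n
    counts = counts[keep]
    if counts.shape[0] < 20:
        raise ValueError(f"profile {name}: fewer than 20 usable columns")
    nres = counts.sum(axis=1, keepdims=True)
    # frequency-based blend: invariant under duplicating the input set
    freq = counts / np.maximum(nres, 1)
    p = (freq + PSEUDOCOUNT * BACKGROUND) / (1.0 + PSEUDOCOUNT)
    scores = 2.0 * np.log2(p / BACKGROUND)
    matrix = np.zeros((counts.shape[0], 21), dtype=np.float32)
    matrix[:, :20] = scores.astype(np.float32)
    return MarkerProfile(name=name, matrix=matrix, background=BACKGROUND.copy())


def _star_alignment(proteins) -> list[str]:
    """Align every member globally to the longest member (free end gaps)."""
    members = sorted(proteins, key=lambda p: (-len(p.seq), p.id))
    center = members[0]
    ncols = len(center.seq)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    rows = [center.seq]
    for member in members[1:]:
        if member.seq == center.seq:
            rows.append(member.seq)
            continue
        aln = aligner.align(center.seq, member.seq)[0]
        row = ["-"] * ncols
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            for off in range(t1 - t0):
                row[t0 + off] = member.seq[q0 + off]
        rows.append("".join(row))
    return rows


def build_profile(proteins, name: str) -> MarkerProfile:
    """Build a marker profile from unaligned proteins via star alignment.

    The longest protein (ties broken lexicographically by id) is the star
    center; insertions relative to the center are discarded; columns with
    more than 50% gaps are dropped.
    """
    if not proteins:
        raise ValueError("cannot build a profile from zero proteins")
    return profile_from_alignment(name, _star_alignment(proteins))


def calibrate_profile(
    profile: MarkerProfile, n_decoys: int = 1000, decoy_len: int = 400, seed: int = 0
) -> MarkerProfile:
    """Fit a Gumbel null to decoy scores; returns a calibrated copy.

    Decoys are i.i.d. draws from the background frequencies. At least 100
    decoys are required for a stable maximum-likelihood fit.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys < 100 gives an unstable Gumbel fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        decoy = rng.choice(20, size=decoy_len, p=profile.background).astype(np.uint8)
        scores[i], _, _ = profile_local_dp(profile.matrix, decoy, GAP_OPEN, GAP_EXT)
    loc, scale = gumbel_r.fit(scores)
    return replace(profile, calibration=(float(loc), float(scale)))


def score_protein(profile: MarkerProfile, seq: str) -> tuple[float, int, int]:
    """Best local alignment score of the profile against one protein."""
    score, s0, s1 = profile_local_dp(profile.matrix, encode_aa(seq.upper()), GAP_OPEN, GAP_EXT)
    return float(score), int(s0), int(s1)


def search_profile(
    profile: MarkerProfile,
    proteins: list[ProteinRecord],
    min_score: float = DEFAULT_MIN_SCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[MarkerHit]:
    """Search a calibrated profile against proteins.

    E-value = N * P(S >= s) under the fitted Gumbel null, with N the
    number of searched proteins. Hits must pass both the score and the
    E-value cutoff; sorted by score descending, ties by protein id.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name} is not calibrated; run calibrate_profile")
    loc, scale = profile.calibration
    n = len(proteins)
    hits: list[MarkerHit] = []
    for prot in proteins:
        score, s0, s1 = score_protein(profile, prot.seq)
        if score < min_score:
            continue
        evalue = float(n * gumbel_r.sf(score, loc, scale))
        if evalue <= max_evalue:
            hits.append(
                MarkerHit(
                    protein_id=prot.id,
                    contig_id=prot.contig_id,
                    profile_name=profile.name,
                    score=score,
                    evalue=evalue,
                    align_start=s0,
                    align_end=s1,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.protein_id))
    return hits


def load_seed_profiles() -> dict[str, MarkerProfile]:
    """Load the packaged seed marker alignments (synthetic stand-ins for the
    Viral_Rep and Phage_F domain families) as uncalibrated profiles."""
    out = {}
    data = importlib.resources.files("viropipe.data")
    for marker in sorted(MARKER_CLASS):
        path = data / f"{marker}.synthetic.afa"
        records = read_fasta(str(path), alphabet="protein")
        out[marker] = profile_from_alignment(marker, [r.seq for r in records])
    return out


def _marker_of(profile_name: str) -> str:
    for marker in MARKER_CLASS:
        if profile_name.startswith(marker):
            return marker
    raise ValueError(f"profile {profile_name!r} maps to no known marker")


def classify_contig(contig: ContigRecord, marker: str) -> str:
    """Apply the circularity/size windows to a marker hit on a contig."""
    cls = MARKER_CLASS[marker]
    window = MICRO_WINDOW if cls == "Microviridae" else CRESS_WINDOW
    if contig.circular and window[0] <= contig.length <= window[1]:
        return cls
    return "flagged-only"


def two_step_ssdna(
    contigs: list[ContigRecord],
    proteins: list[ProteinRecord],
    seed_profiles: dict[str, MarkerProfile],
    min_score: float = DEFAULT_MIN_SCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    calibration_seed: int = 0,
    n_decoys: int = 1000,
) -> tuple[list[SsdnaCall], dict[str, MarkerProfile], list[tuple[str, list[MarkerHit]]]]:
    """Two-step ssDNA identification.

    Step 1 searches the seed profiles against proteins of circular contigs
    only. Step 2 builds one new profile per marker from the step-1 hit
    proteins and searches it against all proteins. Final calls are the
    union of both steps, classified by the circularity/size windows.

    Returns (calls, bootstrapped profiles, conflicts); a contig hit by
    both marker types is reported in conflicts and excluded from calls.
    """
    if not seed_profiles:
        raise ValueError("no seed profiles supplied")
    by_contig = {c.id: c for c in contigs}
    circular_ids = {c.id for c in contigs if c.circular}
    circ_proteins = [p for p in proteins if p.contig_id in circular_ids]
    prot_by_id = {p.id: p for p in proteins}

    marker_hits: dict[str, list[MarkerHit]] = {}
    boot_profiles: dict[str, MarkerProfile] = {}
    for i, marker in enumerate(sorted(seed_profiles)):
        prof = seed_profiles[marker]
        if prof.calibration is None:
            prof = calibrate_profile(prof, n_decoys=n_decoys, seed=calibration_seed + i)
        step1 = search_profile(prof, circ_proteins, min_score, max_evalue)
        hits = {h.protein_id: h for h in step1}
        if step1:
            train = [prot_by_id[pid] for pid in sorted({h.protein_id for h in step1})]
            boot = build_profile(train, name=f"{marker}_boot")
            boot = calibrate_profile(boot, n_decoys=n_decoys, seed=calibration_seed + 100 + i)
            boot_profiles[f"{marker}_boot"] = boot
            for h in search_profile(boot, proteins, min_score, max_evalue):
                prev = hits.get(h.protein_id)
                if prev is None or h.score > prev.score:
                    hits[h.protein_id] = h
        marker_hits[marker] = sorted(hits.values(), key=lambda h: (-h.score, h.protein_id))

    per_contig: dict[str, dict[str, MarkerHit]] = {}
    for marker, hits in marker_hits.items():
        for h in hits:
            slot = per_contig.setdefault(h.contig_id, {})
            if marker not in slot or h.score > slot[marker].score:
                slot[marker] = h
    calls: list[SsdnaCall] = []
    conflicts: list[tuple[str, list[MarkerHit]]] = []
    for contig_id in sorted(per_contig):
        slot = per_contig[contig_id]
        if len(slot) > 1:
            conflicts.append((contig_id, sorted(slot.values(), key=lambda h: -h.score)))
            continue
        marker, hit = next(iter(slot.items()))
        contig = by_contig[contig_id]
        calls.append(
            SsdnaCall(contig_id=contig_id, call_class=classify_contig(contig, marker), supporting_hit=hit)
        )
    return calls, boot_profiles, conflicts
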