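"""Read recruitment to vOTU representatives and abundance estimation.

Each mate is placed independently at its best seeded position on either
strand and retained iff its full-length alignment identity is >= the
cutoff (default 90%). Abundances follow the standard virome
normalization: mean depth (mapped bases over representative length)
scaled per Gbp of metagenome, zeroed where reads cover less than a
threshold fraction of the representative (default 10%), the detection
rule that separates "present" from spurious recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import build_kmer_index, encode_nt, recruit_reads
from .io import ReadPair, SequenceRecord

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_THRESHOLD_PCT = 10.0
RECRUIT_K = 13
RECRUIT_SEED_STEP = 6
RECRUIT_BAND = 5


@dataclass
class CoverageProfile:
    """Per-position depth of one representative in one sample."""

    votu_id: str
    sample_id: str
    depth: np.ndarray
    mapped_bases: int
    mapped_reads: int

    def covered_fraction(self) -> float:
        return 100.0 * float((self.depth > 0).sum()) / self.depth.shape[0]


@dataclass
class AbundanceMatrix:
    """vOTU x sample abundances with the detection threshold applied.

    values[i, j] is mean depth per Gbp of metagenome, set to 0 wherever
    covered_fraction[i, j] < threshold_pct. sample_bases holds total read
    bases per sample (the normalization denominator).
    """

    values: pd.DataFrame
    covered_fraction: pd.DataFrame
    threshold_pct: float
    sample_bases: dict[str, int]

    def log10_view(self) -> pd.DataFrame:
        """Display transform: log10 of detected abundances, zeros masked."""
        return self.values.where(self.values > 0).apply(np.log10)

    def detections(self) -> pd.Series:
        return (self.values > 0).sum(axis=0)


class RepresentativeSet:
    """Concatenated, k-mer indexed representative sequences."""

    def __init__(self, representatives: list[SequenceRecord], k: int = RECRUIT_K):
        if not representatives:
            raise ValueError("no representative sequences")
        self.records = sorted(representatives, key=lambda r: r.id)
        self.k = k
        parts = []
        bounds = [0]
        for rec in self.records:
            parts.append(encode_nt(rec.seq))
            parts.append(np.full(1, 4, dtype=np.uint8))  # separator
            bounds.append(bounds[-1] + len(rec.seq) + 1)
        self.concat = np.concatenate(parts)
        self.bounds = np.asarray(bounds, dtype=np.int64)
        self.sk, self.sp = build_kmer_index(self.concat, k)

    def ref_of(self, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bounds, pos, side="right") - 1


def recruit(
    reads: list[ReadPair],
    representatives: list[SequenceRecord] | RepresentativeSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    sample_id: str = "sample",
) -> tuple[dict[str, CoverageProfile], pd.DataFrame]:
    """Map both mates of every pair to their best representative placement.

    Returns per-representative coverage profiles and a per-read placement
    table (read_id, votu_id or NA, identity). Mates are mapped
    independently; multi-mapping resolves to the single best placement
    with ties broken by representative id then leftmost coordinate.
    """
    rset = representatives if isinstance(representatives, RepresentativeSet) else RepresentativeSet(representatives)
    if not reads:
        raise ValueError("no reads to recruit")
    L = len(reads[0].seq1)
    mats = []
    ids = []
    for p in reads:
        for mate, seq in (("1", p.seq1), ("2", p.seq2)):
            if len(seq) != L:
                raise ValueError("recruit requires uniform read length")
            mats.append(encode_nt(seq))
            ids.append(f"{p.id}/{mate}")
    reads_arr = np.vstack(mats)
    depth = np.zeros(rset.concat.shape[0], dtype=np.int32)
    starts, idents, strands = recruit_reads(
        reads_arr, rset.concat, rset.sk, rset.sp, rset.k, RECRUIT_SEED_STEP,
        np.float32(min_identity), RECRUIT_BAND, depth,
    )
    mapped = starts >= 0
    ref_idx = np.full(starts.shape[0], -1, dtype=np.int64)
    ref_idx[mapped] = rset.ref_of(starts[mapped])
    profiles: dict[str, CoverageProfile] = {}
    for i, rec in enumerate(rset.records):
        lo, hi = int(rset.bounds[i]), int(rset.bounds[i + 1]) - 1
        d = depth[lo:hi].copy()
        n_reads = int((ref_idx == i).sum())
        profiles[rec.id] = CoverageProfile(
            votu_id=rec.id, sample_id=sample_id, depth=d,
            mapped_bases=int(d.sum()), mapped_reads=n_reads,
        )
    placements = pd.DataFrame(
        {
            "read_id": ids,
            "votu_id": [rset.records[j].id if j >= 0 else pd.NA for j in ref_idx],
            "identity": idents,
        }
    )
    return profiles, placements


def quantify(
    profiles: dict[str, dict[str, CoverageProfile]],
    sample_bases: dict[str, int],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> AbundanceMatrix:
    """Normalized abundances from coverage profiles.

    profiles: sample_id -> votu_id -> CoverageProfile. Abundance =
    (mapped_bases / length) * (1e9 / sample_total_bases), zeroed where the
    covered fraction is below threshold_pct.
    """
    samples = sorted(profiles)
    if not samples:
        raise ValueError("no coverage profiles")
    votus = sorted({v for s in samples for v in profiles[s]})
    values = pd.DataFrame(0.0, index=votus, columns=samples)
    cf = pd.DataFrame(0.0, index=votus, columns=samples)
    for s in samples:
        total = sample_bases[s]
        if total == 0:
            raise ValueError(f"sample {s}: zero total bases")
        for v, prof in profiles[s].items():
            length = prof.depth.shape[0]
            cf.loc[v, s] = prof.covered_fraction()
            values.loc[v, s] = (prof.mapped_bases / length) * (1e9 / total)
    values = values.where(cf >= threshold_pct, 0.0)
    return AbundanceMatrix(
        values=values, covered_fraction=cf, threshold_pct=threshold_pct,
        sample_bases=dict(sample_bases),
    )


def threshold_sweep(
    profiles: dict[str, dict[str, CoverageProfile]],
    sample_bases: dict[str, int],
    thresholds: list[float],
) -> dict[float, AbundanceMatrix]:
    """One AbundanceMatrix per covered-fraction threshold (sorted ascending)."""
    return {t: quantify(profiles, sample_bases, threshold_pct=t) for t in sorted(thresholds)}
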