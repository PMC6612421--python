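"""vOTU dereplication by ANI / aligned fraction.

Viral populations (vOTUs) follow the community standard: contigs
clustered greedily at >= 95% ANI over >= 85% of the shorter contig, with
the longest member as representative. dsDNA eligibility comes from the
external viral-category annotation (tiers 1-2, plus tier 3 in
"sensitive" mode); ssDNA eligibility from the marker-based calls; the
>10 kb dsDNA size rule is applied to representatives after clustering,
so a shorter contig can still be absorbed into a large population.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._kernels import encode_nt
from .align import MIN_ANI_LEN, SubjectIndex, chain_identity
from .profiles import SsdnaCall
from .screen import ContigRecord

DEFAULT_MIN_ANI = 95.0
DEFAULT_MIN_AF = 85.0
DSDNA_MIN_REP_LEN = 10_000


@dataclass(frozen=True)
class VOTU:
    """A dereplicated viral population."""

    votu_id: str
    representative_id: str
    member_ids: tuple[str, ...]
    votu_class: str  # dsDNA | Microviridae | CRESS | unknown
    representative_length: int


def greedy_cluster(
    contigs: list[ContigRecord],
    min_ani: float = DEFAULT_MIN_ANI,
    min_af: float = DEFAULT_MIN_AF,
    votu_class: str = "unknown",
    prefix: str = "votu",
) -> list[VOTU]:
    """Greedy length-sorted dereplication.

    Contigs are sorted by length descending (ties by id); each contig
    joins the first existing vOTU whose representative it matches at
    ANI >= min_ani and AF >= min_af (AF on the shorter sequence, i.e. the
    candidate), else it seeds a new vOTU. The sort makes the result
    invariant to input order.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    reps: list[tuple[ContigRecord, SubjectIndex, list[str]]] = []
    for contig in ordered:
        placed = False
        if contig.length >= MIN_ANI_LEN:
            q = encode_nt(contig.seq)
            for rep, idx, members in reps:
                ani, af, _, _ = chain_identity(q, idx)
                if ani >= min_ani and af >= min_af:
                    members.append(contig.id)
                    placed = True
                    break
        if not placed:
            reps.append((contig, SubjectIndex(contig.seq), [contig.id]))
    return [
        VOTU(
            votu_id=f"{prefix}_{i:04d}",
            representative_id=rep.id,
            member_ids=tuple(members),
            votu_class=votu_class,
            representative_length=rep.length,
        )
        for i, (rep, _, members) in enumerate(reps)
    ]


def select_votus(
    contigs: list[ContigRecord],
    ssdna_calls: list[SsdnaCall],
    mode: str = "conservative",
) -> dict[str, list[ContigRecord]]:
    """Partition contigs into per-class vOTU-eligible sets.

    dsDNA: viral-category 1/2 ("conservative") or 1/2/3 ("sensitive")
    contigs not already called ssDNA. ssDNA classes come from the marker
    calls; flagged-only contigs are not eligible.
    """
    if mode not in ("conservative", "sensitive"):
        raise ValueError(f"unknown mode {mode!r}")
    categories = {1, 2} if mode == "conservative" else {1, 2, 3}
    call_by_contig = {c.contig_id: c.call_class for c in ssdna_calls}
    out: dict[str, list[ContigRecord]] = {"dsDNA": [], "Microviridae": [], "CRESS": []}
    for contig in contigs:
        cls = call_by_contig.get(contig.id)
        if cls in ("Microviridae", "CRESS"):
            out[cls].append(contig)
        elif cls is None and contig.viral_category in categories:
            out["dsDNA"].append(contig)
    return out


def cluster_all(
    eligible: dict[str, list[ContigRecord]],
    min_ani: float = DEFAULT_MIN_ANI,
    min_af: float = DEFAULT_MIN_AF,
) -> list[VOTU]:
    """Cluster each class independently; apply the >10 kb dsDNA rule
    to representatives post-clustering."""
    votus: list[VOTU] = []
    for cls in ("dsDNA", "Microviridae", "CRESS"):
        group = eligible.get(cls, [])
        if not group:
            continue
        clustered = greedy_cluster(group, min_ani, min_af, votu_class=cls, prefix=cls.lower())
        if cls == "dsDNA":
            clustered = [v for v in clustered if v.representative_length > DSDNA_MIN_REP_LEN]
        votus.extend(clustered)
    return votus


def votu_table(votus: list[VOTU]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "votu_id": v.votu_id,
                "class": v.votu_class,
                "representative_id": v.representative_id,
                "representative_length": v.representative_length,
                "n_members": len(v.member_ids),
                "member_ids": ",".join(v.member_ids),
            }
            for v in votus
        ],
        columns=["votu_id", "class", "representative_id", "representative_length", "n_members", "member_ids"],
    )
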