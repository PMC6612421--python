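"""Synthetic soil-virome community generator.

Emulates the statistical structure of peat-soil viromes so every
downstream stage is testable without external sequencing data: a dominant
community of linear dsDNA phage genomes (>10 kb), circular Microviridae
genomes (4-8 kb) carrying a capsid-like marker ORF, circular CRESS
genomes (1-5 kb) carrying a Rep-like marker ORF, and lab-contaminant
spike-ins derived from packaged PhiX/M13-like references. Abundances are
lognormal within class, with the ssDNA classes rescaled so their expected
read share matches a target (default 4%, the share observed in soil
viromes where both virus types co-occur). Treatment effects emulate
sample preparation: coverage depletion (CsCl particle purification),
ssDNA dropout (bead-beating lysis), and random genome dropout
(extraction-kit bias).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReadPair, SequenceRecord, read_fasta
from .screen import ContigRecord

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_COMP = str.maketrans("ACGTN", "TGCAN")

SSDNA_CLASSES = ("Microviridae", "CRESS")

TRUTH_COLUMNS = [
    "id", "class", "length", "circular", "true_relative_abundance",
    "marker_start", "marker_end", "viral_category",
]


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic community."""

    n_dsdna: int = 30
    n_micro: int = 3
    n_cress: int = 10
    n_contaminant: int = 2
    abundance_sigma: float = 1.0
    ssdna_read_fraction_target: float = 0.04
    read_length: int = 100
    n_read_pairs: int = 200_000
    per_base_error: float = 0.01
    seed: int = 0
    dsdna_length_range: tuple[int, int] = (10_001, 25_000)
    micro_length_range: tuple[int, int] = (4_000, 8_000)
    cress_length_range: tuple[int, int] = (1_000, 5_000)
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    marker_divergence_max: float = 0.10
    contaminant_divergence_max: float = 0.02
    p_category3: float = 0.0
    terminal_repeat_len: int = 30

    def __post_init__(self):
        if min(self.n_dsdna, self.n_micro, self.n_cress, self.n_contaminant) < 0:
            raise ValueError("community counts must be >= 0")
        if not 0.0 <= self.ssdna_read_fraction_target <= 1.0:
            raise ValueError("ssdna_read_fraction_target must be in [0, 1]")
        if not 0.0 <= self.per_base_error <= 0.2:
            raise ValueError("per_base_error must be in [0, 0.2]")


@dataclass(frozen=True)
class TreatmentEffect:
    """A sample-preparation effect applied to read simulation."""

    coverage_depletion_factor: float = 1.0
    ssdna_dropout: bool = False
    extraction_dropout_rate: float = 0.0

    def __post_init__(self):
        if self.coverage_depletion_factor < 1.0:
            raise ValueError("coverage_depletion_factor must be >= 1")
        if not 0.0 <= self.extraction_dropout_rate <= 1.0:
            raise ValueError("extraction_dropout_rate must be in [0, 1]")


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mutate_protein(rng: np.random.Generator, seq: str, divergence: float) -> str:
    s = list(seq)
    nmut = int(round(divergence * len(s)))
    if nmut == 0:
        return seq
    idx = rng.choice(len(s), size=nmut, replace=False)
    for i in idx:
        if i == 0:
            continue  # keep the initiator methionine
        s[i] = _AA20[(_AA20.index(s[i]) + int(rng.integers(1, 20))) % 20]
    return "".join(s)


def _mutate_nt(rng: np.random.Generator, seq: str, divergence: float) -> str:
    s = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    nmut = int(round(divergence * len(s)))
    idx = rng.choice(len(s), size=nmut, replace=False)
    lut = {ord(a): [ord(b) for b in "ACGT" if b != a] for a in "ACGT"}
    for i in idx:
        choices = lut.get(int(s[i]))
        if choices:
            s[i] = choices[int(rng.integers(3))]
    return s.tobytes().decode()


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[a][int(rng.integers(len(_CODONS[a])))] for a in protein)


def _marker_consensus(marker: str) -> str:
    data = importlib.resources.files("viropipe.data")
    records = read_fasta(str(data / f"{marker}.synthetic.afa"), alphabet="protein")
    return records[0].seq.replace("-", "")


def generate_genomes(spec: CommunitySpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate the community's genomes and its ground-truth table.

    Microviridae and CRESS genomes each carry one marker ORF: the
    packaged marker consensus mutated at up to `marker_divergence_max`
    amino-acid divergence, reverse-translated and embedded in frame with
    an immediately preceding in-frame stop (so the ORF caller reports the
    marker from its own start codon). Contaminants are the packaged
    PhiX/M13-like references mutated at up to 2% nucleotide divergence.
    """
    if spec.n_dsdna + spec.n_micro + spec.n_cress + spec.n_contaminant == 0:
        raise ValueError("empty community: all genome counts are zero")
    rng = np.random.default_rng(spec.seed)
    genomes: list[SequenceRecord] = []
    rows = []

    def add(rec, cls, circular, marker=(None, None), category=None):
        genomes.append(rec)
        rows.append(
            {
                "id": rec.id, "class": cls, "length": len(rec.seq), "circular": circular,
                "true_relative_abundance": np.nan,
                "marker_start": marker[0], "marker_end": marker[1],
                "viral_category": category,
            }
        )

    for i in range(spec.n_dsdna):
        L = int(rng.integers(spec.dsdna_length_range[0], spec.dsdna_length_range[1] + 1))
        if rng.random() < spec.p_category3:
            cat = 3
        else:
            cat = 1 if rng.random() < 0.6 else 2
        add(SequenceRecord(id=f"dsdna_{i:03d}", seq=_rand_nt(rng, L)), "dsDNA", False, category=cat)

    marker_specs = [
        ("Microviridae", "phage_f_like", spec.n_micro, spec.micro_length_range, "micro"),
        ("CRESS", "viral_rep_like", spec.n_cress, spec.cress_length_range, "cress"),
    ]
    for cls, marker, count, (lo, hi), prefix in marker_specs:
        if count == 0:
            continue
        consensus = _marker_consensus(marker)
        cds_len = 3 * (len(consensus) + 1) + 3  # stop + CDS(with stop)
        for i in range(count):
            L = int(rng.integers(max(lo, cds_len + 202), hi + 1))
            divergence = float(rng.uniform(0.02, spec.marker_divergence_max))
            protein = _mutate_protein(rng, consensus, divergence)
            cds = "TAA" + _reverse_translate(rng, protein) + "TAA"
            pos = int(rng.integers(100, L - len(cds) - 100))
            seq = _rand_nt(rng, pos) + cds + _rand_nt(rng, L - pos - len(cds))
            marker_iv = (pos + 3, pos + len(cds))
            add(SequenceRecord(id=f"{prefix}_{i:03d}", seq=seq), cls, True, marker=marker_iv)

    if spec.n_contaminant:
        data = importlib.resources.files("viropipe.data")
        refs = read_fasta(str(data / "contaminants.synthetic.fasta"))
        for i in range(spec.n_contaminant):
            base = refs[i % len(refs)]
            divergence = float(rng.uniform(0.002, spec.contaminant_divergence_max))
            add(
                SequenceRecord(id=f"contam_{i:03d}", seq=_mutate_nt(rng, base.seq, divergence)),
                "contaminant", False,
            )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["viral_category"] = truth["viral_category"].astype("Int64")
    return genomes, truth


def assign_abundances(
    truth: pd.DataFrame,
    spec: CommunitySpec,
    rng: np.random.Generator | None = None,
    sigma: float | None = None,
    base: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw within-class lognormal abundances and rescale ssDNA to target.

    The rescaling equalizes the *length-weighted* (read-fraction) share of
    the ssDNA classes to ``spec.ssdna_read_fraction_target``. ``base``
    optionally multiplies the draws (used to correlate samples within a
    group); ``sigma`` overrides ``spec.abundance_sigma``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    sigma = spec.abundance_sigma if sigma is None else sigma
    t = spec.ssdna_read_fraction_target
    out = truth.copy()
    n = len(out)
    draws = rng.lognormal(mean=0.0, sigma=sigma, size=n) if sigma > 0 else np.ones(n)
    if base is not None:
        draws = draws * np.asarray(base, dtype=float)
    a = draws / draws.sum()
    is_ss = out["class"].isin(SSDNA_CLASSES).to_numpy()
    if t > 0 and not is_ss.any():
        raise ValueError("ssDNA read-fraction target > 0 but community has no ssDNA genomes")
    if is_ss.any():
        w = a * out["length"].to_numpy()
        w_ss = w[is_ss].sum()
        w_other = w[~is_ss].sum()
        if t == 0:
            a[is_ss] = 0.0
        elif w_other == 0:
            pass  # all-ssDNA community: fraction is 1 regardless
        else:
            s = t * w_other / ((1.0 - t) * w_ss)
            a = a.astype(float)
            a[is_ss] *= s
        a = a / a.sum()
    out["true_relative_abundance"] = a
    return out


def simulate_reads(
    genomes: list[SequenceRecord],
    truth: pd.DataFrame,
    spec: CommunitySpec,
    effect: TreatmentEffect | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate inward-facing mate pairs from the community.

    Genomes are chosen proportionally to length-weighted abundance after
    applying the treatment effect; fragment starts are uniform along each
    genome, wrapping the origin for circular genomes; substitution errors
    are applied at ``per_base_error``. Read ids encode the genome of
    origin (``<sample>:<genome>:<n>``) so truth is recoverable.
    """
    effect = effect or TreatmentEffect()
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    if truth["true_relative_abundance"].isna().any():
        raise ValueError("abundances not assigned; run assign_abundances first")
    a = truth["true_relative_abundance"].to_numpy().astype(float)
    lengths = truth["length"].to_numpy()
    w = a * lengths
    is_ss = truth["class"].isin(SSDNA_CLASSES).to_numpy()
    if effect.ssdna_dropout:
        w = np.where(is_ss, 0.0, w)
    if effect.extraction_dropout_rate > 0:
        w = np.where(rng.random(len(w)) < effect.extraction_dropout_rate, 0.0, w)
    if w.sum() <= 0:
        raise ValueError("treatment effect removed every genome from the library")
    active = w > 0
    if spec.read_length > lengths[active].min():
        raise ValueError("read_length exceeds the shortest sampled genome")
    n_pairs = int(round(spec.n_read_pairs / effect.coverage_depletion_factor))
    counts = rng.multinomial(n_pairs, w / w.sum())
    pairs: list[ReadPair] = []
    L_read = spec.read_length
    err = spec.per_base_error
    alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}

    def add_errors(seq: str) -> str:
        if err == 0:
            return seq
        mask = rng.random(len(seq)) < err
        if not mask.any():
            return seq
        s = list(seq)
        for i in np.nonzero(mask)[0]:
            s[i] = alt[s[i]][int(rng.integers(3))]
        return "".join(s)

    qual = "I" * L_read
    serial = 0
    for g, c in zip(genomes, counts):
        if c == 0:
            continue
        row = truth.loc[truth["id"] == g.id].iloc[0]
        L = len(g.seq)
        circular = bool(row["circular"])
        doubled = g.seq + g.seq if circular else g.seq
        frags = np.clip(
            np.round(rng.normal(spec.insert_mean, spec.insert_sd, size=c)).astype(int), L_read, L
        )
        if circular:
            starts = rng.integers(0, L, size=c)
        else:
            starts = (rng.random(c) * (L - frags + 1)).astype(int)
        for frag_len, start in zip(frags, starts):
            frag = doubled[start : start + frag_len]
            m1 = add_errors(frag[:L_read])
            m2 = add_errors(_revcomp(frag[-L_read:]))
            pairs.append(
                ReadPair(id=f"{sample_id}:{g.id}:{serial}", seq1=m1, seq2=m2, qual1=qual, qual2=qual)
            )
            serial += 1
    sample_truth = truth.copy()
    sample_truth["read_pairs"] = counts
    sample_truth["sample_id"] = sample_id
    return pairs, sample_truth


def emit_contigs(
    genomes: list[SequenceRecord],
    truth: pd.DataFrame,
    terminal_repeat_len: int | None = None,
    fragment: dict[str, int] | None = None,
) -> list[ContigRecord]:
    """Emit each genome as one contig (a stand-in for assembly).

    Circular genomes are linearized with a direct terminal repeat so
    circularity is re-detectable downstream; viral-category annotations
    are copied from the truth table. ``fragment`` optionally splits named
    genomes into >= 2 linear pieces without a terminal repeat (emulating
    incomplete assembly).
    """
    repeat = 30 if terminal_repeat_len is None else terminal_repeat_len
    fragment = fragment or {}
    by_id = truth.set_index("id")
    contigs: list[ContigRecord] = []
    for g in genomes:
        row = by_id.loc[g.id]
        cat = row["viral_category"]
        category = int(cat) if pd.notna(cat) else None
        npieces = fragment.get(g.id, 0)
        if npieces >= 2:
            bounds = np.linspace(0, len(g.seq), npieces + 1).astype(int)
            for i in range(npieces):
                contigs.append(
                    ContigRecord(
                        id=f"{g.id}|frag{i}", seq=g.seq[bounds[i] : bounds[i + 1]],
                        viral_category=category,
                    )
                )
            continue
        seq = g.seq + g.seq[:repeat] if bool(row["circular"]) else g.seq
        contigs.append(ContigRecord(id=g.id, seq=seq, viral_category=category))
    return contigs
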