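"""End-to-end orchestration: simulate -> screen -> identify -> cluster ->
recruit -> stats, with a JSON config and a machine-readable run report.

Every stochastic stage derives its generator from the run seed, so a
re-run with the same config reproduces all artifacts byte-identically
(timestamps excluded from artifacts).
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import io as _io
from . import profiles as _profiles
from . import recruit as _recruit_mod
from . import screen as _screen
from . import stats as _stats
from . import synth as _synth
from .synth import CommunitySpec, TreatmentEffect

log = logging.getLogger("viropipe")


@dataclass(frozen=True)
class SampleConfig:
    id: str
    group: int = 0
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)


def _default_samples() -> tuple[SampleConfig, ...]:
    return tuple(
        SampleConfig(id=f"s{i + 1:02d}", group=i // 3) for i in range(6)
    )


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds plus the synthetic community specification."""

    synthetic: CommunitySpec = field(default_factory=CommunitySpec)
    samples: tuple[SampleConfig, ...] = field(default_factory=_default_samples)
    mode: str = "conservative"
    min_repeat: int = 20
    min_orf_aa: int = 30
    contaminant_min_ani: float = 95.0
    contaminant_min_af: float = 80.0
    marker_min_score: float = 50.0
    marker_max_evalue: float = 1e-3
    cluster_min_ani: float = 95.0
    cluster_min_af: float = 85.0
    recruit_min_identity: float = 90.0
    detection_thresholds: tuple[float, ...] = (10.0,)
    primary_threshold: float = 10.0
    n_boot: int = 1000
    group_sigma_within: float = 0.35

    def __post_init__(self):
        if self.mode not in ("conservative", "sensitive"):
            raise ValueError(f"mode must be conservative or sensitive, got {self.mode!r}")
        for name, val, lo, hi in [
            ("contaminant_min_ani", self.contaminant_min_ani, 0, 100),
            ("contaminant_min_af", self.contaminant_min_af, 0, 100),
            ("cluster_min_ani", self.cluster_min_ani, 0, 100),
            ("cluster_min_af", self.cluster_min_af, 0, 100),
            ("recruit_min_identity", self.recruit_min_identity, 0, 100),
        ]:
            if not lo <= val <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        for t in self.detection_thresholds:
            if not 0 <= t <= 100:
                raise ValueError("detection thresholds must be in [0, 100]")
        if self.min_repeat < 10:
            raise ValueError("min_repeat < 10 would call spurious circularity")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "synthetic" in raw:
            synth = {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["synthetic"].items()
            }
            raw["synthetic"] = CommunitySpec(**synth)
        if "samples" in raw:
            raw["samples"] = tuple(
                SampleConfig(
                    id=s["id"], group=s.get("group", 0),
                    effect=TreatmentEffect(**s.get("effect", {})),
                )
                for s in raw["samples"]
            )
        if "detection_thresholds" in raw:
            raw["detection_thresholds"] = tuple(raw["detection_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _version() -> str:
    try:
        return importlib.metadata.version("viropipe")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def load_contaminant_db() -> list[_io.SequenceRecord]:
    data = importlib.resources.files("viropipe.data")
    return _io.read_fasta(str(data / "contaminants.synthetic.fasta"))


def simulate_samples(config: RunConfig, genomes, truth):
    """Per-sample read simulation with group-correlated abundances.

    Each group draws a base abundance profile; samples jitter it with a
    smaller within-group lognormal, so samples cluster by group the way
    replicate soil cores cluster by core.
    """
    spec = config.synthetic
    group_base: dict[int, np.ndarray] = {}
    for s in config.samples:
        if s.group not in group_base:
            g_rng = np.random.default_rng([spec.seed, 900 + s.group])
            group_base[s.group] = _synth.assign_abundances(truth, spec, rng=g_rng)[
                "true_relative_abundance"
            ].to_numpy()
    out = {}
    for i, s in enumerate(config.samples):
        rng = np.random.default_rng([spec.seed, 10 + i])
        truth_s = _synth.assign_abundances(
            truth, spec, rng=rng, sigma=config.group_sigma_within, base=group_base[s.group]
        )
        reads, sample_truth = _synth.simulate_reads(
            genomes, truth_s, spec, effect=s.effect, rng=rng, sample_id=s.id
        )
        out[s.id] = (reads, sample_truth)
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; writes all artifacts under ``outdir``.

    Returns the run report (also written as run_report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.synthetic
    report: dict = {"version": _version(), "config": config.to_dict(), "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("simulate")
    genomes, truth = _synth.generate_genomes(spec)
    contigs_raw = _synth.emit_contigs(genomes, truth, spec.terminal_repeat_len)
    _io.write_fasta(genomes, outdir / "genomes.fasta")
    _io.write_fasta(
        [_io.SequenceRecord(id=c.id, seq=c.seq) for c in contigs_raw], outdir / "contigs.fasta"
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    samples = simulate_samples(config, genomes, truth)
    (outdir / "reads").mkdir(exist_ok=True)
    sample_bases = {}
    for sid, (reads, sample_truth) in samples.items():
        _io.write_fastq_pairs(reads, outdir / "reads" / f"{sid}_R1.fastq", outdir / "reads" / f"{sid}_R2.fastq")
        sample_truth.to_csv(outdir / "reads" / f"{sid}_truth.tsv", sep="\t", index=False)
        sample_bases[sid] = 2 * spec.read_length * len(reads)
    done("simulate")

    stage("screen")
    screened = [
        _screen.detect_circularity(
            _io.SequenceRecord(id=c.id, seq=c.seq), config.min_repeat, viral_category=c.viral_category
        )
        for c in contigs_raw
    ]
    kept, removed = _screen.screen_contaminants(
        screened, load_contaminant_db(), config.contaminant_min_ani, config.contaminant_min_af
    )
    removed.to_csv(outdir / "contaminants_removed.tsv", sep="\t", index=False)
    report["stages"]["screen"] = {
        "contigs_in": len(screened),
        "contaminants_removed": int(len(removed)),
        "circular": sum(c.circular for c in kept),
    }
    done("screen")

    stage("ssdna")
    proteins = [p for c in kept for p in _screen.call_orfs(c, config.min_orf_aa)]
    calls, boot_profiles, conflicts = _profiles.two_step_ssdna(
        kept, proteins, _profiles.load_seed_profiles(),
        min_score=config.marker_min_score, max_evalue=config.marker_max_evalue,
        calibration_seed=spec.seed,
    )
    pd.DataFrame(
        [
            {
                "contig_id": c.contig_id, "class": c.call_class,
                "profile": c.supporting_hit.profile_name,
                "score": c.supporting_hit.score, "evalue": c.supporting_hit.evalue,
            }
            for c in calls
        ],
        columns=["contig_id", "class", "profile", "score", "evalue"],
    ).to_csv(outdir / "ssdna_calls.tsv", sep="\t", index=False)
    by_class = pd.Series([c.call_class for c in calls]).value_counts().to_dict() if calls else {}
    report["stages"]["ssdna"] = {
        "proteins": len(proteins),
        "calls": {k: int(v) for k, v in by_class.items()},
        "conflicts": len(conflicts),
    }
    done("ssdna")

    stage("cluster")
    eligible = _cluster.select_votus(kept, calls, mode=config.mode)
    votus = _cluster.cluster_all(eligible, config.cluster_min_ani, config.cluster_min_af)
    table = _cluster.votu_table(votus)
    table.to_csv(outdir / "votus.tsv", sep="\t", index=False)
    contig_by_id = {c.id: c for c in kept}
    reps = [
        _io.SequenceRecord(id=v.votu_id, seq=contig_by_id[v.representative_id].seq) for v in votus
    ]
    if reps:
        _io.write_fasta(reps, outdir / "votu_representatives.fasta")
    report["stages"]["cluster"] = {
        "votus": {
            cls: int((table["class"] == cls).sum()) for cls in ("dsDNA", "Microviridae", "CRESS")
        }
    }
    done("cluster")

    stage("recruit")
    profiles_by_sample: dict[str, dict[str, _recruit_mod.CoverageProfile]] = {}
    matrices = {}
    if reps:
        rset = _recruit_mod.RepresentativeSet(reps)
        for sid, (reads, _) in samples.items():
            profs, _placements = _recruit_mod.recruit(
                reads, rset, min_identity=config.recruit_min_identity, sample_id=sid
            )
            profiles_by_sample[sid] = profs
        thresholds = sorted(set(config.detection_thresholds) | {config.primary_threshold})
        matrices = _recruit_mod.threshold_sweep(profiles_by_sample, sample_bases, thresholds)
        (outdir / "abundance").mkdir(exist_ok=True)
        for t, mat in matrices.items():
            _io.write_tsv_matrix(mat.values, outdir / "abundance" / f"abundance_t{t:g}.tsv")
            _io.write_tsv_matrix(
                mat.covered_fraction, outdir / "abundance" / f"covered_fraction_t{t:g}.tsv"
            )
        report["stages"]["recruit"] = {
            "detections_per_threshold": {
                f"{t:g}": {k: int(v) for k, v in mat.detections().items()}
                for t, mat in matrices.items()
            }
        }
    done("recruit")

    stage("stats")
    if matrices:
        primary = matrices[config.primary_threshold]
        div = _stats.diversity(primary)
        div.to_csv(outdir / "diversity.tsv", sep="\t")
        bc = _stats.bray_curtis(primary)
        _io.write_tsv_matrix(bc, outdir / "bray_curtis.tsv")
        coords, eigvals = _stats.pcoa(bc)
        coords.to_csv(outdir / "pcoa.tsv", sep="\t")
        if len(config.samples) >= 3:
            tree = _stats.hclust_au(primary, n_boot=config.n_boot, seed=spec.seed)
            _io.write_newick(tree, outdir / "sample_tree.nwk")
            report["stages"]["stats"] = {
                "min_AU": float(tree.nodes["AU"].min()),
                "pcoa_positive_axes": int((eigvals > 0).sum()),
            }
    done("stats")

    report["wall_clock_s"] = timings
    _validate_report(report, len(contigs_raw))
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _validate_report(report: dict, n_contigs: int) -> None:
    votus = report["stages"].get("cluster", {}).get("votus", {})
    if sum(votus.values()) > n_contigs:
        raise AssertionError("report inconsistent: more vOTUs than input contigs")


def compare_treatments(
    arms: list[tuple[str, CommunitySpec, TreatmentEffect]],
    min_identity: float = 90.0,
    threshold_pct: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the same community under different treatment effects.

    All arms must share the community seed (the genomes and abundances
    are identical; only the treatment differs). Returns a per-vOTU table
    of raw mean depths and detections per arm, and a summary with shared
    counts, the mean shared-vOTU coverage ratio of the first arm over
    each other arm, and per-arm ssDNA detections.
    """
    if len(arms) < 2:
        raise ValueError("need at least two treatment arms")
    seeds = {spec.seed for _, spec, _ in arms}
    if len(seeds) != 1:
        raise ValueError("treatment arms must share the community seed")
    name0, spec, _ = arms[0]
    genomes, truth = _synth.generate_genomes(spec)
    truth = _synth.assign_abundances(truth, spec, rng=np.random.default_rng([spec.seed, 1]))
    contigs_raw = _synth.emit_contigs(genomes, truth, spec.terminal_repeat_len)
    screened = [
        _screen.detect_circularity(_io.SequenceRecord(id=c.id, seq=c.seq), viral_category=c.viral_category)
        for c in contigs_raw
    ]
    kept, _removed = _screen.screen_contaminants(screened, load_contaminant_db())
    proteins = [p for c in kept for p in _screen.call_orfs(c)]
    calls, _boot, _conf = _profiles.two_step_ssdna(
        kept, proteins, _profiles.load_seed_profiles(), calibration_seed=spec.seed
    )
    votus = _cluster.cluster_all(_cluster.select_votus(kept, calls))
    contig_by_id = {c.id: c for c in kept}
    ssdna_votus = {v.votu_id for v in votus if v.votu_class in _synth.SSDNA_CLASSES}
    reps = [_io.SequenceRecord(id=v.votu_id, seq=contig_by_id[v.representative_id].seq) for v in votus]
    rset = _recruit_mod.RepresentativeSet(reps)

    table = pd.DataFrame(index=sorted(r.id for r in reps))
    detect = {}
    for k, (name, _spec_k, effect) in enumerate(arms):
        rng = np.random.default_rng([spec.seed, 7000 + k])
        reads, _st = _synth.simulate_reads(genomes, truth, spec, effect=effect, rng=rng, sample_id=name)
        profs, _pl = _recruit_mod.recruit(reads, rset, min_identity=min_identity, sample_id=name)
        mat = _recruit_mod.quantify(
            {name: profs}, {name: 2 * spec.read_length * len(reads)}, threshold_pct
        )
        table[f"depth_{name}"] = [
            profs[v].mapped_bases / profs[v].depth.shape[0] for v in table.index
        ]
        table[f"detected_{name}"] = (mat.values[name] > 0).reindex(table.index).to_numpy()
        detect[name] = mat
    names = [a[0] for a in arms]
    shared = table[[f"detected_{n}" for n in names]].all(axis=1)
    summary: dict = {
        "votus_total": len(table),
        "shared_votus": int(shared.sum()),
        "unique_per_arm": {
            n: int((table[f"detected_{n}"] & ~shared).sum()) for n in names
        },
        "ssdna_detected_per_arm": {
            n: int(sum(table.loc[v, f"detected_{n}"] for v in table.index if v in ssdna_votus))
            for n in names
        },
        "coverage_ratio_vs_first": {},
    }
    ref = names[0]
    for n in names[1:]:
        sub = table[shared & (table[f"depth_{n}"] > 0)]
        ratios = sub[f"depth_{ref}"] / sub[f"depth_{n}"]
        pooled = table.loc[shared, f"depth_{ref}"].sum() / max(table.loc[shared, f"depth_{n}"].sum(), 1e-12)
        summary["coverage_ratio_vs_first"][n] = {
            "mean_of_ratios": float(ratios.mean()) if len(ratios) else float("nan"),
            "pooled_ratio": float(pooled),
            "n_shared": int(len(sub)),
        }
    return table, summary
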