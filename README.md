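# viropipe

Soil-virome informatics: from assembled contigs and quality-controlled
reads to ssDNA/dsDNA vOTU catalogues, read-recruitment abundance
matrices, and community statistics — with a synthetic soil-virome
generator so the whole pipeline is testable end to end without external
sequencing data.

## Who this is for

Viral metagenomics ("viromics") of soils is dominated by two practical
problems: tiny, highly divergent ssDNA viruses (Microviridae, CRESS DNA
viruses) are systematically missed by automatic viral-contig classifiers,
and relative abundances are sensitive to detection thresholds and sample
preparation (particle purification, lysis method, extraction kit).
`viropipe` implements the standard desk-side of a soil-virome study as a
reusable, deterministic library plus CLI, for anyone who has contigs with
per-contig viral-category annotations and paired reads and wants vOTU
tables, abundance matrices, diversity indices, ordinations, and
bootstrap-supported sample clustering.

## What it computes

- **Contig screening** — circular contigs detected via direct terminal
  repeats (DTR ≥ 20 nt, trimmed); laboratory contaminants removed at
  > 95% ANI over ≥ 80% of the contig.
- **Two-step ssDNA identification** — seed marker profiles (Rep-like and
  capsid F-like, position-specific scoring matrices in half-bit log-odds
  with decoy-calibrated Gumbel E-values; cutoffs score ≥ 50, E ≤ 0.001)
  are searched against proteins of circular contigs; new profiles built
  from those hits are then searched against *all* predicted proteins.
  Calls are classified by size window: circular 4–8 kb with a capsid hit →
  Microviridae, circular 1–5 kb with a Rep hit → CRESS, anything else
  with a marker hit → flagged-only.
- **vOTU dereplication** — greedy clustering at ≥ 95% ANI over ≥ 85% of
  the shorter contig (aligned fraction), longest member as
  representative; dsDNA vOTUs additionally require a > 10 kb
  representative from annotation tiers 1–2 (tier 3 admitted in
  "sensitive" mode).
- **Read recruitment** — each mate mapped independently at ≥ 90% identity
  over its full length; abundance A = (mapped bases / contig length) ×
  (10⁹ / sample bases), set to 0 where reads cover < 10% of the contig
  (threshold sweepable 0–75%).
- **Community statistics** — richness R, Shannon H (natural log), Pielou
  J = H/ln R; Bray-Curtis dissimilarity; principal coordinate analysis;
  complete-linkage sample clustering with multiscale-bootstrap
  approximately-unbiased (AU) support from 1,000 replicates per scale.
- **Synthetic communities** — lognormal-abundance communities of dsDNA
  phage (> 10 kb), circular marker-bearing Microviridae and CRESS
  genomes, PhiX/M13-like contaminant spike-ins, ssDNA held at a target
  read share (default 4%), plus treatment effects: coverage depletion
  (density-gradient purification), ssDNA dropout (bead-beating lysis),
  and random genome dropout (extraction-kit bias).

## Worked example

```python
import dataclasses, json
from viropipe.pipeline import RunConfig, run_pipeline
from viropipe.synth import CommunitySpec

cfg = dataclasses.replace(
    RunConfig(),
    synthetic=CommunitySpec(n_read_pairs=20_000, seed=11),
    n_boot=200,
)
report = run_pipeline(cfg, "virome_run")
print(json.dumps(report["stages"], indent=2))
```

prints

```json
{
  "screen":  {"contigs_in": 45, "contaminants_removed": 2, "circular": 13},
  "ssdna":   {"proteins": 3645, "calls": {"CRESS": 10, "Microviridae": 3}, "conflicts": 0},
  "cluster": {"votus": {"dsDNA": 30, "Microviridae": 3, "CRESS": 10}},
  "recruit": {"detections_per_threshold": {"10": {"s01": 43, "s02": 43, "s03": 43,
                                                  "s04": 43, "s05": 43, "s06": 43}}},
  "stats":   {"min_AU": 62.11420288277919, "pcoa_positive_axes": 5}
}
```

Reading: the 45 simulated contigs lose the 2 contaminant spike-ins; 13
circular contigs carry ssDNA markers and classify into 10 CRESS + 3
Microviridae; together with the 30 dsDNA contigs they dereplicate into 43
vOTUs, all of which are detected (≥ 10% covered) in each of the six
20,000-pair samples. The same run writes the vOTU table, abundance and
covered-fraction matrices, diversity report, Bray-Curtis matrix, PCoA
coordinates, and an AU/BP-annotated Newick sample tree under
`virome_run/`. The equivalent shell invocation is
`viropipe run --config cfg.json --out virome_run` (see also
`viropipe simulate|screen|ssdna|stats|compare`).

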