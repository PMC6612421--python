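import io as _io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viropipe.io import write_fasta
from viropipe.synth import (
    CommunitySpec,
    TreatmentEffect,
    assign_abundances,
    emit_contigs,
    generate_genomes,
    simulate_reads,
)

from helpers import revcomp

SSDNA = ("Microviridae", "CRESS")


@pytest.mark.parametrize("seed", [0, 1, 7])
def test_class_length_windows_and_flags(seed):
    spec = CommunitySpec(n_dsdna=4, n_micro=3, n_cress=4, n_contaminant=1, seed=seed)
    _, truth = generate_genomes(spec)
    micro = truth[truth["class"] == "Microviridae"]
    cress = truth[truth["class"] == "CRESS"]
    dsdna = truth[truth["class"] == "dsDNA"]
    assert micro["length"].between(4000, 8000).all() and micro["circular"].all()
    assert cress["length"].between(1000, 5000).all() and cress["circular"].all()
    assert (dsdna["length"] > 10000).all() and not dsdna["circular"].any()
    assert dsdna["viral_category"].isin([1, 2]).all()
    assert truth.loc[truth["class"].isin(SSDNA), "marker_start"].notna().all()


def test_same_seed_byte_identical_fasta():
    spec = CommunitySpec(n_dsdna=2, n_micro=1, n_cress=1, n_contaminant=1, seed=5)
    out = []
    for _ in range(2):
        genomes, _ = generate_genomes(spec)
        buf = _io.StringIO()
        for g in genomes:
            buf.write(f">{g.id}\n{g.seq}\n")
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_different_seed_different_sequences_same_counts():
    a, ta = generate_genomes(CommunitySpec(n_dsdna=5, seed=1, n_micro=0, n_cress=0, n_contaminant=0, ssdna_read_fraction_target=0))
    b, tb = generate_genomes(CommunitySpec(n_dsdna=5, seed=2, n_micro=0, n_cress=0, n_contaminant=0, ssdna_read_fraction_target=0))
    assert list(ta["class"]) == list(tb["class"])
    assert all(x.seq != y.seq for x, y in zip(a, b))


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    n_dsdna=st.integers(0, 3),
    n_micro=st.integers(0, 3),
    n_cress=st.integers(0, 3),
    seed=st.integers(0, 2**20),
    sigma=st.floats(0.0, 2.0),
)
def test_class_windows_never_violated(n_dsdna, n_micro, n_cress, seed, sigma):
    """Property: generated genomes always respect their class length windows."""
    if n_dsdna + n_micro + n_cress == 0:
        return
    spec = CommunitySpec(
        n_dsdna=n_dsdna, n_micro=n_micro, n_cress=n_cress, n_contaminant=0,
        abundance_sigma=sigma, seed=seed,
        ssdna_read_fraction_target=0.04 if (n_micro + n_cress) else 0.0,
    )
    _, truth = generate_genomes(spec)
    windows = {"dsDNA": (10_001, 25_000), "Microviridae": (4_000, 8_000), "CRESS": (1_000, 5_000)}
    for _, row in truth.iterrows():
        lo, hi = windows[row["class"]]
        assert lo <= row["length"] <= hi
        assert row["circular"] == (row["class"] in SSDNA)


def test_empty_community_rejected():
    with pytest.raises(ValueError, match="empty community"):
        generate_genomes(CommunitySpec(n_dsdna=0, n_micro=0, n_cress=0, n_contaminant=0))


class TestAbundances:
    def test_ssdna_length_weighted_share_equals_target(self, small_spec, small_community):
        _, truth = small_community
        w = truth["true_relative_abundance"] * truth["length"]
        share = w[truth["class"].isin(SSDNA)].sum() / w.sum()
        assert share == pytest.approx(small_spec.ssdna_read_fraction_target, abs=1e-9)
        assert truth["true_relative_abundance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_target_zero_zeroes_ssdna(self):
        spec = CommunitySpec(n_dsdna=3, n_micro=1, n_cress=1, n_contaminant=0, ssdna_read_fraction_target=0.0)
        _, truth = generate_genomes(spec)
        truth = assign_abundances(truth, spec)
        assert (truth.loc[truth["class"].isin(SSDNA), "true_relative_abundance"] == 0).all()

    def test_sigma_zero_equal_within_class(self):
        spec = CommunitySpec(n_dsdna=4, n_micro=0, n_cress=3, n_contaminant=0, abundance_sigma=0.0)
        _, truth = generate_genomes(spec)
        truth = assign_abundances(truth, spec)
        for cls in ("dsDNA", "CRESS"):
            vals = truth.loc[truth["class"] == cls, "true_relative_abundance"]
            assert vals.nunique() == 1

    def test_unreachable_target_errors(self):
        spec = CommunitySpec(n_dsdna=3, n_micro=0, n_cress=0, n_contaminant=0, ssdna_read_fraction_target=0.04)
        _, truth = generate_genomes(spec)
        with pytest.raises(ValueError, match="no ssDNA"):
            assign_abundances(truth, spec)


class TestReads:
    def test_ssdna_dropout_zero_ssdna_reads(self, small_spec, small_community):
        genomes, truth = small_community
        reads, st = simulate_reads(
            genomes, truth, small_spec, effect=TreatmentEffect(ssdna_dropout=True)
        )
        assert st.loc[st["class"].isin(SSDNA), "read_pairs"].sum() == 0
        assert not any(":micro_" in p.id or ":cress_" in p.id for p in reads)

    def test_depletion_arithmetic(self, small_spec, small_community):
        genomes, truth = small_community
        import dataclasses

        spec = dataclasses.replace(small_spec, n_read_pairs=300_000)
        reads, _ = simulate_reads(
            genomes, truth, spec, effect=TreatmentEffect(coverage_depletion_factor=30.0),
            rng=np.random.default_rng(0),
        )
        assert len(reads) == 10_000

    def test_error_free_reads_are_substrings(self, small_spec, small_community):
        import dataclasses

        genomes, truth = small_community
        spec = dataclasses.replace(small_spec, per_base_error=0.0, n_read_pairs=300)
        reads, _ = simulate_reads(genomes, truth, spec, rng=np.random.default_rng(1))
        doubled = {g.id: g.seq + g.seq for g in genomes}
        for p in reads[:100]:
            gid = p.id.split(":")[1]
            assert p.seq1 in doubled[gid] or revcomp(p.seq1) in doubled[gid]
            assert p.seq2 in doubled[gid] or revcomp(p.seq2) in doubled[gid]

    def test_read_length_longer_than_shortest_genome_errors(self):
        spec = CommunitySpec(
            n_dsdna=1, n_micro=0, n_cress=1, n_contaminant=0, read_length=2000,
            ssdna_read_fraction_target=0.04, cress_length_range=(1000, 1500),
        )
        genomes, truth = generate_genomes(spec)
        truth = assign_abundances(truth, spec)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(genomes, truth, spec)

    def test_realized_ssdna_fraction_converges(self):
        spec = CommunitySpec(
            n_dsdna=8, n_micro=2, n_cress=3, n_contaminant=0, n_read_pairs=60_000, seed=3
        )
        genomes, truth = generate_genomes(spec)
        truth = assign_abundances(truth, spec)
        _, st = simulate_reads(genomes, truth, spec, rng=np.random.default_rng(9))
        frac = st.loc[st["class"].isin(SSDNA), "read_pairs"].sum() / st["read_pairs"].sum()
        t = spec.ssdna_read_fraction_target
        se = np.sqrt(t * (1 - t) / spec.n_read_pairs)
        assert abs(frac - t) < 3 * se


class TestContigs:
    def test_circular_contig_has_terminal_repeat(self, small_community):
        genomes, truth = small_community
        contigs = {c.id: c for c in emit_contigs(genomes, truth, 30)}
        for _, row in truth.iterrows():
            c = contigs[row["id"]]
            if row["circular"]:
                assert c.length == row["length"] + 30
                assert c.seq[:30] == c.seq[-30:]
            else:
                assert c.length == row["length"]

    def test_contaminant_category_none(self, small_community):
        genomes, truth = small_community
        contigs = {c.id: c for c in emit_contigs(genomes, truth)}
        for _, row in truth[truth["class"] == "contaminant"].iterrows():
            assert contigs[row["id"]].viral_category is None

    def test_fragmentation_splits_without_repeat(self, small_community):
        genomes, truth = small_community
        target = truth.loc[truth["class"] == "CRESS", "id"].iloc[0]
        contigs = emit_contigs(genomes, truth, fragment={target: 3})
        frags = [c for c in contigs if c.id.startswith(f"{target}|frag")]
        assert len(frags) == 3
        whole = next(g for g in genomes if g.id == target)
        assert "".join(f.seq for f in frags) == whole.seq
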