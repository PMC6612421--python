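import numpy as np
import pytest
from helpers import mutate_aa
from scipy.stats import gumbel_r, kstest

from viropipe.profiles import (
    BACKGROUND,
    MARKER_CLASS,
    build_profile,
    calibrate_profile,
    load_seed_profiles,
    score_protein,
    search_profile,
    two_step_ssdna,
)
from viropipe._kernels import AA_ORDER, encode_aa
from viropipe.screen import ProteinRecord


def _prot(pid, seq, contig="c0"):
    return ProteinRecord(id=pid, contig_id=contig, frame=1, start=0, end=3 * len(seq), seq=seq)


def _rand_protein(rng, n):
    return "".join(AA_ORDER[i] for i in rng.choice(20, size=n, p=BACKGROUND))


def oracle_local_profile_score(matrix, seq, gap_open=10.0, gap_ext=1.0):
    """Plain-Python affine-gap local profile alignment (Gotoh), no tricks."""
    codes = encode_aa(seq)
    n, m = matrix.shape[0], len(codes)
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            H[i, j] = max(0.0, H[i - 1, j - 1] + matrix[i - 1, codes[j - 1]], E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestBuildProfile:
    def test_single_protein_consensus_identity(self):
        rng = np.random.default_rng(0)
        seq = _rand_protein(rng, 80)
        prof = build_profile([_prot("p0", seq)], "m")
        assert prof.consensus == seq and prof.ncols == 80

    def test_duplicates_match_single(self):
        rng = np.random.default_rng(1)
        seq = _rand_protein(rng, 60)
        p1 = build_profile([_prot("p0", seq)], "m")
        p2 = build_profile([_prot("p0", seq), _prot("p1", seq)], "m")
        np.testing.assert_allclose(p1.matrix, p2.matrix, atol=1e-5)

    def test_consensus_recovers_fixture_consensus(self):
        """Star alignment of 5 mild variants: column majority recovers the source."""
        rng = np.random.default_rng(2)
        cons = _rand_protein(rng, 100)
        members = [_prot(f"p{i}", mutate_aa(rng, cons, 0.08)) for i in range(5)]
        prof = build_profile(members, "m")
        mismatches = sum(a != b for a, b in zip(prof.consensus, cons))
        assert mismatches <= 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], "m")


@pytest.fixture(scope="module")
def calibrated():
    prof = load_seed_profiles()["viral_rep_like"]
    return calibrate_profile(prof, n_decoys=400, decoy_len=200, seed=1)


@pytest.fixture(scope="module")
def profile_and_member():
    rng = np.random.default_rng(5)
    seq = _rand_protein(rng, 110)
    members = [_prot(f"p{i}", mutate_aa(rng, seq, 0.05)) for i in range(4)]
    prof = calibrate_profile(build_profile(members, "viral_rep_like_test"), n_decoys=300, seed=2)
    return prof, members[0]


class TestCalibration:
    def test_determinism(self):
        prof = load_seed_profiles()["viral_rep_like"]
        a = calibrate_profile(prof, n_decoys=150, decoy_len=150, seed=9)
        b = calibrate_profile(prof, n_decoys=150, decoy_len=150, seed=9)
        assert a.calibration == b.calibration

    def test_too_few_decoys_rejected(self):
        prof = load_seed_profiles()["viral_rep_like"]
        with pytest.raises(ValueError, match="100"):
            calibrate_profile(prof, n_decoys=50)

    def test_decoy_pvalues_uniform(self, calibrated):
        """Fresh decoys scored under the fitted null give ~Uniform(0,1) p-values."""
        rng = np.random.default_rng(33)
        loc, scale = calibrated.calibration
        pvals = []
        for _ in range(300):
            decoy = "".join(AA_ORDER[i] for i in rng.choice(20, size=200, p=BACKGROUND))
            s, _, _ = score_protein(calibrated, decoy)
            pvals.append(gumbel_r.sf(s, loc, scale))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_decoy_evalue_pass_rate_bounded(self, calibrated):
        rng = np.random.default_rng(44)
        n = 400
        loc, scale = calibrated.calibration
        passed = 0
        for _ in range(n):
            decoy = "".join(AA_ORDER[i] for i in rng.choice(20, size=200, p=BACKGROUND))
            s, _, _ = score_protein(calibrated, decoy)
            if n * gumbel_r.sf(s, loc, scale) <= 1e-3 and s >= 50:
                passed += 1
        assert passed / n <= 0.005


class TestSearch:
    def test_self_hit_passes_cutoffs(self, profile_and_member):
        prof, member = profile_and_member
        hits = search_profile(prof, [member])
        assert len(hits) == 1 and hits[0].protein_id == member.id
        assert hits[0].score >= 50 and hits[0].evalue <= 1e-3

    def test_shuffled_decoys_yield_no_hits(self, profile_and_member):
        prof, member = profile_and_member
        rng = np.random.default_rng(6)
        decoys = [
            _prot(f"d{i}", "".join(rng.permutation(list(member.seq)))) for i in range(200)
        ]
        assert search_profile(prof, decoys) == []

    def test_diverged_member_still_hit(self, profile_and_member):
        prof, member = profile_and_member
        rng = np.random.default_rng(7)
        far = _prot("far", mutate_aa(rng, member.seq, 0.15))
        hits = search_profile(prof, [far])
        assert [h.protein_id for h in hits] == ["far"]

    def test_uncalibrated_profile_rejected(self):
        rng = np.random.default_rng(8)
        prof = build_profile([_prot("p", _rand_protein(rng, 60))], "m")
        with pytest.raises(ValueError, match="calibrated"):
            search_profile(prof, [_prot("q", _rand_protein(rng, 60))])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_matches_bruteforce_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cons = _rand_protein(rng, 40)
        prof = build_profile([_prot(f"p{i}", mutate_aa(rng, cons, 0.1)) for i in range(3)], "m")
        target = mutate_aa(rng, cons, 0.2) + _rand_protein(rng, 25)
        got, _, _ = score_protein(prof, target)
        want = oracle_local_profile_score(prof.matrix, target)
        assert got == pytest.approx(want, abs=1e-3)


class TestTwoStep:
    def test_full_recovery_on_synthetic_community(self, small_contigs, small_community):
        from viropipe.screen import call_orfs, screen_contaminants
        from viropipe.pipeline import load_contaminant_db

        _, truth = small_community
        kept, _ = screen_contaminants(small_contigs, load_contaminant_db())
        proteins = [p for c in kept for p in call_orfs(c)]
        calls, boot, conflicts = two_step_ssdna(
            kept, proteins, load_seed_profiles(), calibration_seed=3, n_decoys=300
        )
        got = {(c.contig_id, c.call_class) for c in calls}
        want = {
            (row["id"], row["class"])
            for _, row in truth[truth["class"].isin(MARKER_CLASS.values())].iterrows()
        }
        assert got == want and conflicts == []
        assert set(boot) == {"phage_f_like_boot", "viral_rep_like_boot"}

    def test_linearized_cress_flagged_only(self, small_spec, small_community):
        from viropipe.io import SequenceRecord
        from viropipe.screen import call_orfs, detect_circularity
        from viropipe.synth import emit_contigs

        genomes, truth = small_community
        target = truth.loc[truth["class"] == "CRESS", "id"].iloc[0]
        raw = emit_contigs(genomes, truth)
        # strip the terminal repeat of one CRESS genome: it stays linear
        by_id = {g.id: g for g in genomes}
        raw = [
            c if c.id != target else type(c)(id=c.id, seq=by_id[target].seq, viral_category=c.viral_category)
            for c in raw
        ]
        contigs = [
            detect_circularity(SequenceRecord(id=c.id, seq=c.seq), viral_category=c.viral_category)
            for c in raw
        ]
        proteins = [p for c in contigs for p in call_orfs(c)]
        calls, _, _ = two_step_ssdna(
            contigs, proteins, load_seed_profiles(), calibration_seed=3, n_decoys=300
        )
        by_id = {c.contig_id: c.call_class for c in calls}
        assert by_id.get(target) == "flagged-only"

    def test_dsdna_only_community_empty_calls(self):
        from viropipe.io import SequenceRecord
        from viropipe.screen import call_orfs, detect_circularity
        from viropipe.synth import CommunitySpec, emit_contigs, generate_genomes

        spec = CommunitySpec(
            n_dsdna=3, n_micro=0, n_cress=0, n_contaminant=0, ssdna_read_fraction_target=0, seed=9
        )
        genomes, truth = generate_genomes(spec)
        contigs = [
            detect_circularity(SequenceRecord(id=c.id, seq=c.seq), viral_category=c.viral_category)
            for c in emit_contigs(genomes, truth)
        ]
        proteins = [p for c in contigs for p in call_orfs(c)]
        calls, boot, conflicts = two_step_ssdna(
            contigs, proteins, load_seed_profiles(), calibration_seed=3, n_decoys=300
        )
        assert calls == [] and boot == {} and conflicts == []

    def test_no_seed_profiles_rejected(self, small_contigs):
        with pytest.raises(ValueError, match="seed profiles"):
            two_step_ssdna(small_contigs, [], {})
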