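"""PWM construction, scoring, thresholding, scanning, discovery, comparison."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from regulonkit.core_model import PromoterRegion
from regulonkit.motif import (
    PWM,
    build_pwm,
    consensus_distance,
    detection_floor,
    discover_palindromic_motif,
    motif_similarity,
    read_meme,
    score_pvalue_table,
    score_site,
    scan_region,
    training_threshold,
    write_meme,
)

from conftest import random_sequence


def region_from(seq: str, anchor_offset: int | None = None) -> PromoterRegion:
    return PromoterRegion(
        anchor_operon_id="op", contig_id="chr", interval=(0, len(seq)),
        sequence=seq, offset_of_start_codon=anchor_offset if anchor_offset is not None else len(seq),
    )


class TestBuildPWM:
    def test_hand_computed_log_odds(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=1.0, symmetrize=False)
        # freq(A) = (2+1)/(2+4) = 0.5 -> log2(0.5/0.25) = 1 bit per column
        assert pwm.log_odds[:, 0] == pytest.approx([1.0, 1.0])

    def test_background_frequencies_give_zero_log_odds(self):
        pwm = build_pwm(["AC", "CA", "GT", "TG"], pseudocount=0.0, symmetrize=False)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_symmetrize_enforces_palindromic_invariant(self):
        rng = np.random.default_rng(2)
        sites = [random_sequence(16, rng) for _ in range(7)]
        pwm = build_pwm(sites, symmetrize=True)
        assert pwm.is_palindromic(tol=1e-9)

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_pwm([])

    def test_unequal_lengths_name_offender(self):
        with pytest.raises(ValueError, match="ACG"):
            build_pwm(["ACGT", "ACG"])

    def test_sites_with_n_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            build_pwm(["ACNT"])


class TestScoreSite:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(freqs=np.full((6, 4), 0.25))
        assert score_site(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        pwm = PWM(freqs=np.full((6, 4), 0.25))
        with pytest.raises(ValueError, match="length"):
            score_site(pwm, "ACGT")

    def test_consensus_is_argmax_by_exhaustive_enumeration(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.5, symmetrize=False)
        scores = {
            "".join(w): score_site(pwm, "".join(w))
            for w in itertools.product("ACGT", repeat=4)
        }
        assert max(scores, key=scores.get) == "ACGT"
        assert scores["ACGT"] == pytest.approx(pwm.log_odds.max(axis=1).sum())

    def test_palindromic_pwm_is_strand_flip_invariant(self):
        rng = np.random.default_rng(4)
        pwm = build_pwm([random_sequence(18, rng) for _ in range(5)], symmetrize=True)
        for _ in range(200):
            s = random_sequence(18, rng)
            rc = str(Seq(s).reverse_complement())
            assert score_site(pwm, s) == pytest.approx(score_site(pwm, rc), abs=1e-9)


class TestTrainingThreshold:
    def test_threshold_is_minimum_training_score(self):
        rng = np.random.default_rng(1)
        sites = [random_sequence(14, rng) for _ in range(6)]
        pwm = build_pwm(sites)
        thr = training_threshold(pwm, sites)
        assert thr == pytest.approx(min(score_site(pwm, s) for s in sites))
        assert pwm.threshold == thr

    def test_single_site_threshold_is_its_own_score(self):
        sites = ["ACGTACGTACGTAC"]
        pwm = build_pwm(sites)
        assert training_threshold(pwm, sites) == pytest.approx(score_site(pwm, sites[0]))

    def test_empty_training_set_rejected(self):
        pwm = build_pwm(["ACGT"])
        with pytest.raises(ValueError, match="empty"):
            training_threshold(pwm, [])

    def test_training_sites_always_recovered_by_rescan(self):
        rng = np.random.default_rng(9)
        consensus = "TTGATCCACGTGGATCAA"
        promoters, sites = [], []
        for _ in range(6):
            seq = random_sequence(200, rng)
            pos = int(rng.integers(0, 200 - 18))
            site = "".join(
                c if rng.random() < 0.9 else rng.choice([b for b in "ACGT" if b != c])
                for c in consensus
            )
            seq = seq[:pos] + site + seq[pos + 18 :]
            promoters.append(region_from(seq))
            sites.append(site)
        pwm = build_pwm(sites)
        training_threshold(pwm, sites)
        for region, site in zip(promoters, sites):
            hits = scan_region(pwm, region)
            assert site in [h.sequence for h in hits]


class TestScanRegion:
    def test_minus_infinity_threshold_hits_every_window(self):
        rng = np.random.default_rng(3)
        pwm = build_pwm([random_sequence(14, rng) for _ in range(3)])
        pwm.threshold = -1e9
        region = region_from(random_sequence(100, rng))
        assert len(scan_region(pwm, region)) == 100 - 14 + 1

    def test_unset_threshold_rejected(self):
        pwm = build_pwm(["ACGTACGTACGTAC"])
        with pytest.raises(ValueError, match="threshold"):
            scan_region(pwm, region_from("ACGT" * 20))

    def test_windows_containing_n_are_skipped(self):
        rng = np.random.default_rng(3)
        pwm = build_pwm([random_sequence(14, rng) for _ in range(3)])
        pwm.threshold = -1e9
        seq = random_sequence(100, rng)
        seq = seq[:50] + "N" + seq[51:]
        hits = scan_region(pwm, region_from(seq))
        assert len(hits) == (100 - 14 + 1) - 14
        assert all("N" not in h.sequence for h in hits)

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(8)
        pwm = build_pwm([random_sequence(16, rng) for _ in range(4)])
        region = region_from(random_sequence(300, rng))
        pwm.threshold = -1e9
        all_scores = sorted(h.score for h in scan_region(pwm, region))
        prev = None
        for thr in np.linspace(min(all_scores), max(all_scores) + 1, 100):
            pwm.threshold = float(thr)
            hits = {(h.interval, round(h.score, 6)) for h in scan_region(pwm, region)}
            if prev is not None:
                assert hits <= prev
            prev = hits

    def test_planted_consensus_found_at_exact_coordinate(self):
        rng = np.random.default_rng(12)
        consensus = "TGAAACCACGTGGTTTCA"
        seq = random_sequence(400, rng)
        seq = seq[:137] + consensus + seq[137 + 18 :]
        pwm = build_pwm([consensus])
        training_threshold(pwm, [consensus])
        hits = scan_region(pwm, region_from(seq))
        assert any(h.interval == (137, 155) for h in hits)


class TestNullDistribution:
    def test_dp_survival_matches_exhaustive_enumeration(self):
        pwm = build_pwm(["ACGT", "AGGT", "ACGA"], symmetrize=False)
        grid, survival = score_pvalue_table(pwm, bin_width=0.01)
        # exact enumeration over all 256 windows under uniform background
        exact = [
            (score_site(pwm, "".join(w)), 0.25 ** 4)
            for w in itertools.product("ACGT", repeat=4)
        ]
        for t in (-4.0, 0.0, 2.0, 4.0):
            truth = sum(p for s, p in exact if s >= t - 0.03)
            dp = float(survival[np.searchsorted(grid, t - 0.03)])
            assert dp == pytest.approx(truth, abs=0.02)

    def test_detection_floor_rises_with_scan_size(self):
        rng = np.random.default_rng(0)
        pwm = build_pwm([random_sequence(18, rng) for _ in range(10)])
        assert detection_floor(pwm, 10_000) <= detection_floor(pwm, 1_000_000)


class TestDiscovery:
    def _planted_promoters(self, consensus, n, rng, corruption=0.0, length=260):
        promoters = []
        w = len(consensus)
        for _ in range(n):
            seq = random_sequence(length, rng)
            pos = int(rng.integers(0, length - w))
            site = "".join(
                c if rng.random() >= corruption
                else rng.choice([b for b in "ACGT" if b != c])
                for c in consensus
            )
            promoters.append(region_from(seq[:pos] + site + seq[pos + w :]))
        return promoters

    def test_exact_planted_palindrome_recovered(self):
        rng = np.random.default_rng(21)
        consensus = "TTGTAAGCGCTTACAA"  # 16-bp palindrome
        assert consensus == str(Seq(consensus).reverse_complement())
        promoters = self._planted_promoters(consensus, 10, rng)
        result = discover_palindromic_motif(promoters, seed=21)
        assert result.pwm.width == 16
        assert consensus_distance(result.pwm.consensus, consensus) <= 1
        assert not result.low_confidence

    def test_pure_background_is_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        promoters = [region_from(random_sequence(260, rng)) for _ in range(10)]
        result = discover_palindromic_motif(promoters, seed=5)
        assert result.low_confidence
        # information content sits below the planted-motif regime (~1.3 bits/col)
        assert result.mean_ic_per_column < 1.0

    def test_discovery_is_seed_deterministic(self):
        rng = np.random.default_rng(33)
        consensus = "ACGATCCACGTGGATCGT"
        promoters = self._planted_promoters(consensus, 8, rng, corruption=0.1)
        r1 = discover_palindromic_motif(promoters, seed=99)
        r2 = discover_palindromic_motif(promoters, seed=99)
        assert np.array_equal(r1.pwm.freqs, r2.pwm.freqs)
        assert r1.pwm.threshold == r2.pwm.threshold

    def test_single_promoter_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            discover_palindromic_motif([region_from("ACGT" * 30)], seed=0)

    def test_short_promoter_named_in_error(self):
        rng = np.random.default_rng(0)
        short = region_from("ACGTACGT")
        short.anchor_operon_id = "tiny_op"
        good = region_from(random_sequence(260, rng))
        with pytest.raises(ValueError, match="tiny_op"):
            discover_palindromic_motif([good, short], seed=0)


class TestMotifSimilarity:
    def test_identical_pwms_score_one(self):
        rng = np.random.default_rng(7)
        pwm = build_pwm([random_sequence(18, rng) for _ in range(5)])
        assert motif_similarity(pwm, pwm) == pytest.approx(1.0)

    def test_reverse_complement_scores_one(self):
        rng = np.random.default_rng(7)
        pwm = build_pwm([random_sequence(18, rng) for _ in range(5)], symmetrize=False)
        rc = PWM(freqs=pwm.freqs[::-1][:, [3, 2, 1, 0]])
        assert motif_similarity(pwm, rc) == pytest.approx(1.0)

    def test_width_gap_beyond_four_incomparable(self):
        a = PWM(freqs=np.full((14, 4), 0.25))
        b = PWM(freqs=np.full((20, 4), 0.25))
        assert motif_similarity(a, b) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(13)
        a = build_pwm([random_sequence(18, rng) for _ in range(4)])
        b = build_pwm([random_sequence(16, rng) for _ in range(4)])
        assert motif_similarity(a, b) == pytest.approx(motif_similarity(b, a))

    def test_random_pairs_stay_far_below_grouping_threshold(self):
        """Sampling oracle (frozen): the max-over-alignments statistic on
        independent width-20 frequency motifs averages ~0.25 and never
        approaches the tau=0.8 grouping regime."""
        rng = np.random.default_rng(0)
        vals = [
            motif_similarity(
                PWM(freqs=rng.dirichlet(np.ones(4), size=20)),
                PWM(freqs=rng.dirichlet(np.ones(4), size=20)),
            )
            for _ in range(300)
        ]
        assert 0.15 <= float(np.mean(vals)) <= 0.35
        assert max(vals) < 0.7


class TestMemeRoundTrip:
    def test_write_read_preserves_matrix_and_threshold(self, tmp_path):
        rng = np.random.default_rng(3)
        sites = [random_sequence(16, rng) for _ in range(5)]
        pwm = build_pwm(sites)
        training_threshold(pwm, sites)
        pwm.name = "test_motif"
        write_meme([pwm], tmp_path / "m.meme")
        back = read_meme(tmp_path / "m.meme")
        assert len(back) == 1
        assert back[0].name == "test_motif"
        assert np.allclose(back[0].freqs, pwm.freqs, atol=1e-5)
        assert back[0].threshold == pytest.approx(pwm.threshold, abs=1e-5)
        assert back[0].palindromic


class TestConsensusDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "ACGTACGT", 0),
            ("ACGTACGT", "ACGTACGA", 1),
            ("ACGT", "ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA")), 0),
            ("ACGTACGTAC", "ACGTACGT", 2),  # width difference counts
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert consensus_distance(a, b) == expected
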