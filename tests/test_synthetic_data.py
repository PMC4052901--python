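"""Simulator contracts: determinism, planted-site arithmetic, ground truth."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from regulonkit.core_model import extract_promoter
from regulonkit.motif import build_pwm, score_site
from regulonkit.synthetic_data import (
    SimulationConfig,
    evaluate_recovery,
    generate_palindromic_consensus,
    simulate_pangenome,
)

from conftest import make_member
from regulonkit.reconstruction import Regulon


class TestPalindromicConsensus:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        width=st.sampled_from([14, 16, 18, 20, 22, 24]),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_even_width_output_is_self_reverse_complement(self, width, seed):
        s = generate_palindromic_consensus(width, seed=seed)
        assert len(s) == width
        assert s == str(Seq(s).reverse_complement())
        assert s[width // 2 - 1 : width // 2 + 1] == "CG"

    def test_width_two_is_the_central_pair(self):
        assert generate_palindromic_consensus(2, "CG", seed=0) == "CG"

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            generate_palindromic_consensus(17, "CG", seed=0)

    def test_non_complementary_central_pair_rejected(self):
        with pytest.raises(ValueError, match="central pair"):
            generate_palindromic_consensus(16, "AC", seed=0)


class TestSimulatePangenome:
    def test_seed_determinism_is_byte_identical(self):
        cfg = SimulationConfig(seed=11, n_genomes=3, n_genes=20)
        g1, t1 = simulate_pangenome(cfg)
        g2, t2 = simulate_pangenome(SimulationConfig(seed=11, n_genomes=3, n_genes=20))
        assert [g.contigs for g in g1] == [g.contigs for g in g2]
        assert [g.proteins for g in g1] == [g.proteins for g in g2]
        assert [(s.genome_id, s.interval, s.sequence) for s in t1.planted_sites] == [
            (s.genome_id, s.interval, s.sequence) for s in t2.planted_sites
        ]
        assert t1.planted_consensus == t2.planted_consensus

    def test_site_count_arithmetic(self):
        cfg = SimulationConfig(
            seed=3, n_genomes=5, n_regulated_operons=4, sites_per_operon=1,
            gene_loss_rate=0.0, autoregulation_prob=1.0, decoy_rate=0.0,
        )
        _, truth = simulate_pangenome(cfg)
        assert len(truth.planted_sites) == 5 * (4 + 1)

    def test_zero_corruption_plants_exact_consensus(self):
        cfg = SimulationConfig(seed=5, motif_conserved_fraction=1.0, decoy_rate=0.0)
        _, truth = simulate_pangenome(cfg)
        assert all(s.sequence == truth.planted_consensus for s in truth.planted_sites)
        # and they score maximally under the consensus-trained PWM
        pwm = build_pwm([truth.planted_consensus], symmetrize=True)
        top = pwm.max_score()
        for s in truth.planted_sites:
            assert score_site(pwm, s.sequence) == pytest.approx(top, abs=1e-9)

    def test_planted_sites_lie_inside_anchor_promoter_window(self, default_clade):
        genomes, truth = default_clade
        by_id = {g.genome_id: g for g in genomes}
        for s in truth.planted_sites:
            genome = by_id[s.genome_id]
            anchor = genome.gene(s.anchor_first_gene)
            region = extract_promoter(genome, anchor)
            lo, hi = region.interval
            assert lo <= s.interval[0] and s.interval[1] <= hi
            assert -400 <= s.offset_center <= 100
            # the oriented window exposes the planted (oriented) sequence
            if anchor.strand == "+":
                j = s.interval[0] - lo
            else:
                j = hi - s.interval[1]
            w = s.interval[1] - s.interval[0]
            assert region.sequence[j : j + w] == s.sequence

    def test_infeasible_contig_length_fails_before_output(self):
        cfg = SimulationConfig(seed=1, n_genomes=2, contig_length=1000)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_pangenome(cfg)

    def test_invalid_motif_width_rejected(self):
        with pytest.raises(ValueError, match="motif_width"):
            SimulationConfig(motif_width=12).validate()

    def test_too_many_regulated_operons_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=10, n_regulated_operons=50)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_pangenome(cfg)

    def test_orthology_map_covers_every_gene(self, default_clade):
        genomes, truth = default_clade
        for genome in genomes:
            for gene in genome.genes:
                assert gene.gene_id in truth.orthology_map

    def test_one_tf_per_genome_unless_lost(self, default_clade):
        genomes, truth = default_clade
        for genome in genomes:
            tfs = genome.tf_genes
            assert len(tfs) <= 1
            if tfs:
                assert truth.tf_genes[genome.genome_id] == tfs[0].gene_id


class TestEvaluateRecovery:
    def _reconstruction_from_truth(self, truth):
        regs = {}
        for s in truth.planted_sites:
            reg = regs.setdefault(s.genome_id, Regulon(tf_gene_id="", genome_id=s.genome_id))
            member = make_member(s.genome_id, s.anchor_operon_id, [s.anchor_first_gene])
            member.sites[0].interval = s.interval
            reg.members.append(member)
        return list(regs.values())

    def test_perfect_reconstruction_scores_one(self, default_clade):
        _, truth = default_clade
        m = evaluate_recovery(truth, self._reconstruction_from_truth(truth),
                              consensus=truth.planted_consensus)
        assert m.site_precision == 1.0 and m.site_recall == 1.0
        assert m.operon_precision == 1.0 and m.operon_recall == 1.0
        assert m.consensus_distance == 0

    def test_empty_reconstruction_has_null_precision(self, default_clade):
        _, truth = default_clade
        m = evaluate_recovery(truth, [])
        assert m.site_precision is None
        assert m.site_recall == 0.0
        assert m.operon_recall == 0.0

    def test_hand_counted_three_of_four_plus_spurious(self, default_clade):
        _, truth = default_clade
        # keep 3 recovered sites of one genome, add 1 spurious
        gid = truth.planted_sites[0].genome_id
        mine = [s for s in truth.planted_sites if s.genome_id == gid][:4]
        assert len(mine) == 4
        reg = Regulon(tf_gene_id="", genome_id=gid)
        for s in mine[:3]:
            member = make_member(gid, s.anchor_operon_id, [s.anchor_first_gene])
            member.sites[0].interval = s.interval
            reg.members.append(member)
        spurious = make_member(gid, f"{gid}:bogus", ["no_such_gene"])
        spurious.sites[0].interval = (1, 19)
        reg.members.append(spurious)
        truth_subset = type(truth)(
            planted_consensus=truth.planted_consensus,
            planted_sites=mine,
            decoy_sites=[],
            true_regulons={gid: {s.anchor_first_gene for s in mine}},
            orthology_map=truth.orthology_map,
            tf_genes=truth.tf_genes,
        )
        m = evaluate_recovery(truth_subset, [reg])
        assert m.site_precision == pytest.approx(0.75)
        assert m.site_recall == pytest.approx(0.75)
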