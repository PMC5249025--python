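import pytest

from tatascreen.screen import run_screen
from tatascreen.simulate import EFFECTS, SimSpec, SimSpecError, simulate
from tatascreen.variants import DELETION_TOKEN


class TestDeterminism:
    def test_same_seed_reproduces_everything(self, cfg):
        a = simulate(SimSpec(seed=1, n_promoters=10), cfg)
        b = simulate(SimSpec(seed=1, n_promoters=10), cfg)
        assert a.promoters_fasta() == b.promoters_fasta()
        assert a.snp_contexts == b.snp_contexts
        assert a.truth.equals(b.truth)

    def test_disjoint_seeds_give_distinct_sequences(self, cfg):
        a = simulate(SimSpec(seed=1, n_promoters=10), cfg)
        b = simulate(SimSpec(seed=2, n_promoters=10), cfg)
        assert a.promoters_fasta() != b.promoters_fasta()

    def test_snp_streams_do_not_perturb_sequences(self, cfg):
        """Changing the SNP-type mix must leave the promoter sequences alone
        (sequences and SNP placement use independent named random streams)."""
        a = simulate(SimSpec(seed=5, n_promoters=8), cfg)
        b = simulate(
            SimSpec(seed=5, n_promoters=8, snp_mix={"substitution": 1.0}), cfg
        )
        assert [p.seq for _, p in a.promoters] == [p.seq for _, p in b.promoters]


class TestValidation:
    def test_region_shorter_than_window_rejected(self, cfg):
        with pytest.raises(SimSpecError, match="window"):
            simulate(SimSpec(seed=1, region_length=20), cfg)

    def test_jitter_overflowing_region_rejected(self, cfg):
        with pytest.raises(SimSpecError, match="region"):
            simulate(SimSpec(seed=1, tata_center_offset=-21, center_jitter=4), cfg)

    def test_mix_proportions_must_sum_to_one(self, cfg):
        with pytest.raises(SimSpecError, match="sum to 1"):
            simulate(SimSpec(seed=1, effect_mix={"neutral_flank": 0.5}), cfg)

    def test_unknown_mix_key_rejected(self, cfg):
        with pytest.raises(SimSpecError, match="unknown"):
            simulate(SimSpec(seed=1, snp_mix={"inversion": 1.0}), cfg)

    def test_gc_background_bounds(self, cfg):
        with pytest.raises(SimSpecError, match="gc_background"):
            simulate(SimSpec(seed=1, gc_background=1.0), cfg)


class TestGroundTruth:
    def test_truth_table_covers_every_snp(self, cfg):
        res = simulate(SimSpec(seed=3, n_promoters=30), cfg)
        assert len(res.truth) == 30
        assert set(res.truth["effect"]) <= set(EFFECTS)
        assert list(res.truth["rsid"]) == [c.rsid for c in res.snp_contexts]

    def test_neutral_snps_sit_far_from_the_box(self, cfg):
        res = simulate(
            SimSpec(seed=4, n_promoters=25, effect_mix={"neutral_flank": 1.0}), cfg
        )
        half_window = (cfg.window_length + 1) // 2
        motif_len = cfg.motif_length
        for _, row in res.truth.iterrows():
            box_center = row.box_start + motif_len // 2
            assert abs(row.position - box_center) >= half_window

    def test_breaking_event_alters_a_consensus_base(self, cfg):
        consensus = cfg.pwm_argmax()
        res = simulate(
            SimSpec(seed=6, n_promoters=25, effect_mix={"consensus_breaking": 1.0}),
            cfg,
        )
        for ctx, (_, row) in zip(res.snp_contexts, res.truth.iterrows()):
            i = row.position - row.box_start
            assert 0 <= i < cfg.motif_length
            if ctx.mut_alleles[0] != DELETION_TOKEN:
                assert ctx.wt[0] == consensus[i]
                assert all(a != consensus[i] for a in ctx.mut_alleles)

    def test_improving_event_restores_the_consensus_base(self, cfg):
        consensus = cfg.pwm_argmax()
        res = simulate(
            SimSpec(seed=7, n_promoters=25, effect_mix={"consensus_improving": 1.0}),
            cfg,
        )
        for ctx, (_, row) in zip(res.snp_contexts, res.truth.iterrows()):
            i = row.position - row.box_start
            assert ctx.wt != consensus[i]
            assert ctx.mut_alleles == (consensus[i],)

    def test_significant_calls_agree_with_intended_effect(self, cfg):
        """Desk-scale ground-truth consistency: screened direction matches the
        planted effect class for every significant record."""
        expected = {"consensus_breaking": "down", "consensus_improving": "up"}
        for effect, direction in expected.items():
            res = simulate(
                SimSpec(seed=8, n_promoters=20, effect_mix={effect: 1.0}), cfg
            )
            screened = run_screen(res.snp_contexts, cfg)
            assert not screened.failures
            significant = [r for r in screened.records if r.direction != "insignificant"]
            assert significant, "planted effects should mostly clear the significance gate"
            assert all(r.direction == direction for r in significant)
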