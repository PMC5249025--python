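import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tatascreen.affinity import (
    BASES,
    AffinityModelConfig,
    ModelConfigError,
    estimate_affinity,
    kd_nanomolar,
    load_model,
    score_window,
    write_model,
)
from tatascreen.variants import PromoterSequence

rng = np.random.default_rng(20260920)


def random_seq(n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def brute_force_max(seq: str, cfg) -> tuple[float, int]:
    """Independent window-max oracle: enumerate every window explicitly."""
    best, best_start = -math.inf, 0
    for i in range(len(seq) - cfg.window_length + 1):
        s = score_window(seq[i : i + cfg.window_length], cfg)
        if s > best:
            best, best_start = s, i
    return best, best_start


class TestKdNanomolar:
    @pytest.mark.parametrize(
        "neg_ln_kd, expected_nM",
        [(9 * math.log(10), 1.0), (9 * math.log(10) - math.log(5), 5.0), (0.0, 1e9)],
    )
    def test_closed_form(self, neg_ln_kd, expected_nM):
        assert kd_nanomolar(neg_ln_kd) == pytest.approx(expected_nM, rel=1e-12)

    def test_strictly_decreasing(self):
        xs = np.linspace(-5, 30, 50)
        ys = [kd_nanomolar(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))


class TestScoreWindow:
    def test_wrong_length_rejected(self, cfg):
        with pytest.raises(ValueError, match="window"):
            score_window("ACGT", cfg)

    def test_deterministic(self, cfg):
        w = random_seq(cfg.window_length)
        assert score_window(w, cfg) == score_window(w, cfg)

    def test_gc_only_window_recognition_floor(self, cfg):
        """A window with no A/T: every motif placement scores identically badly,
        and the window score equals the brute-force minimum over placements."""
        w = "GC" * (cfg.window_length // 2)
        m = cfg.motif_length
        placements = [
            sum(cfg.pwm[i][w[p + i]] for i in range(m))
            for p in range(len(w) - m + 1)
        ]
        c = cfg.linear_coeffs
        expected = (
            c["intercept"]
            + c["recognition"] * max(placements)
            + c["sliding"] * np.mean([cfg.slide_weights[w[i:i+2]] for i in range(len(w) - 1)])
            + c["bending"] * np.mean([cfg.bend_weights[w[i:i+2]] for i in range(len(w) - 1)])
        )
        assert score_window(w, cfg) == pytest.approx(expected, abs=1e-12)
        # no placement can beat the best A/T-free placement by using the motif's
        # preferred bases: check max over placements is attained by enumeration
        assert max(placements) >= min(placements)


class TestEstimateAffinity:
    def test_single_window_degenerate_case(self, cfg):
        w = random_seq(cfg.window_length)
        est = estimate_affinity(PromoterSequence(w), cfg)
        assert est.neg_ln_kd == score_window(w, cfg)
        assert est.best_window_start == 0
        assert len(est.per_window_scores) == 1

    def test_window_max_matches_brute_force_enumeration(self, cfg):
        for _ in range(40):
            seq = random_seq(51)
            est = estimate_affinity(PromoterSequence(seq, origin="synthetic"), cfg)
            best, start = brute_force_max(seq, cfg)
            assert est.neg_ln_kd == best
            assert est.best_window_start == start
            assert est.neg_ln_kd == max(est.per_window_scores)

    def test_kd_consistent_with_neg_ln_kd(self, cfg):
        est = estimate_affinity(PromoterSequence(random_seq(51)), cfg)
        assert est.kd_nM == pytest.approx(math.exp(-est.neg_ln_kd) * 1e9, rel=1e-12)

    def test_adding_flanks_never_decreases_affinity(self, cfg):
        for _ in range(20):
            core = random_seq(51)
            grown = random_seq(7) + core + random_seq(7)
            a = estimate_affinity(PromoterSequence(core), cfg)
            b = estimate_affinity(PromoterSequence(grown), cfg)
            assert b.neg_ln_kd >= a.neg_ln_kd

    def test_short_context_scored_as_truncated_window(self, cfg):
        est = estimate_affinity(PromoterSequence("TTTTGAAAGCCATAAAAACAG"), cfg)  # 21 nt
        assert len(est.per_window_scores) == 1
        assert est.delta == cfg.delta_constant

    def test_below_minimum_length_rejected(self, cfg):
        with pytest.raises(ValueError, match="too short"):
            estimate_affinity(PromoterSequence("ACGTACGTA"), cfg)

    def test_recognition_term_monotone_toward_consensus(self, cfg):
        """Replacing any base of a window with the motif's per-position
        maximal-weight base (at the best placement) never lowers the
        recognition contribution of that placement."""
        consensus = cfg.pwm_argmax()
        m = cfg.motif_length

        def placement_score(w, p):
            return sum(cfg.pwm[i][w[p + i]] for i in range(m))

        for _ in range(20):
            w = random_seq(cfg.window_length)
            p = max(range(len(w) - m + 1), key=lambda p: placement_score(w, p))
            base_score = placement_score(w, p)
            for i in range(m):
                improved = w[: p + i] + consensus[i] + w[p + i + 1 :]
                assert placement_score(improved, p) >= base_score

    def test_window_sd_delta_method(self, cfg):
        alt = AffinityModelConfig(
            window_length=cfg.window_length, pwm=cfg.pwm,
            slide_weights=cfg.slide_weights, bend_weights=cfg.bend_weights,
            linear_coeffs=cfg.linear_coeffs, delta_method="window_sd",
        )
        est = estimate_affinity(PromoterSequence(random_seq(51)), alt)
        assert est.delta > 0


class TestModelConfig:
    def test_default_config_valid(self, cfg):
        assert cfg.window_length >= 10
        assert len(cfg.pwm) == cfg.motif_length
        assert set(cfg.linear_coeffs) == {"intercept", "sliding", "recognition", "bending"}

    def test_round_trip_is_identity(self, cfg, tmp_path):
        path = tmp_path / "model.yaml"
        write_model(cfg, path)
        again = load_model(path)
        assert again == cfg

    def test_incomplete_dinucleotide_table_rejected(self, cfg, tmp_path):
        import yaml
        path = tmp_path / "model.yaml"
        write_model(cfg, path)
        doc = yaml.safe_load(path.read_text())
        del doc["slide_weights"]["AA"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ModelConfigError, match="AA"):
            load_model(path)

    def test_missing_key_rejected(self, cfg, tmp_path):
        import yaml
        path = tmp_path / "model.yaml"
        write_model(cfg, path)
        doc = yaml.safe_load(path.read_text())
        del doc["pwm"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ModelConfigError):
            load_model(path)

    @given(st.sampled_from(["nonsense", "", "window"]))
    @settings(derandomize=True, max_examples=3)
    def test_unknown_delta_method_rejected(self, cfg, method):
        with pytest.raises(ModelConfigError):
            AffinityModelConfig(
                window_length=cfg.window_length, pwm=cfg.pwm,
                slide_weights=cfg.slide_weights, bend_weights=cfg.bend_weights,
                linear_coeffs=cfg.linear_coeffs, delta_method=method,
            )
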