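"""Synthetic cohort generator: calibration, determinism, structural contracts."""

import dataclasses

import numpy as np
import pytest

from dpmkit.core import Outcome, TriState, terminal_confidence, validate
from dpmkit.segmentation import phase_composition, segment
from dpmkit.stats import case_summary, trajectory
from dpmkit.synthetic import (
    ConfigError,
    CountSpec,
    GeneratorConfig,
    _case_rng,
    discretized_pmf,
    generate_case,
    generate_cohort,
    generate_rater_pairs,
    sample_count,
)


class TestCountSpec:
    def test_degenerate_bounds_are_constant(self):
        rng = np.random.default_rng(0)
        spec = CountSpec(3.2, 0.0, 3, 3)
        assert all(sample_count(spec, rng) == 3 for _ in range(10))

    def test_mean_outside_bounds_is_config_error(self):
        with pytest.raises(ConfigError):
            CountSpec(0.5, 1.0, 1, 9).validate()

    def test_bounds_out_of_order_rejected(self):
        with pytest.raises(ConfigError):
            CountSpec(2.0, 1.0, 5, 1).validate()

    @pytest.mark.parametrize(
        "spec",
        [
            CountSpec(3.2, 1.8, 1, 9),
            CountSpec(7.9, 2.9, 3, 17),
            CountSpec(1.76, 0.81, -2, 3),
            CountSpec(-2.5, 2.08, -4, 2),
        ],
    )
    def test_calibrated_pmf_mean_is_exact(self, spec):
        ks, p = discretized_pmf(spec)
        assert float(ks @ p) == pytest.approx(spec.mean, abs=1e-9)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    def test_large_sample_mean_recovers_target(self):
        spec = CountSpec(3.2, 1.8, 1, 9)
        rng = np.random.default_rng(99)
        draws = sample_count(spec, rng, size=100_000)
        # 3 SE of the realized-SD sampling error
        ks, p = discretized_pmf(spec)
        sd = float(np.sqrt(ks**2 @ p - (ks @ p) ** 2))
        assert abs(draws.mean() - 3.2) < 3 * sd / np.sqrt(draws.size)
        assert draws.min() >= 1 and draws.max() <= 9


class TestConfigValidation:
    def test_default_config_is_feasible(self, default_config):
        default_config.validate()

    def test_incompatible_structural_probs_rejected(self):
        cfg = dataclasses.replace(GeneratorConfig(), p_final_in_phase1=0.1, p_phase2_addition=0.2)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_round_trip_through_json(self, tmp_path, default_config):
        path = tmp_path / "config.json"
        default_config.to_json(path)
        assert GeneratorConfig.from_json(path) == default_config

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig.from_dict({"n_cases": 5, "surprise": 1})


class TestGenerateCase:
    def test_same_seed_gives_identical_case(self, default_config):
        a = generate_case(default_config, _case_rng(7, 0), "x")
        b = generate_case(default_config, _case_rng(7, 0), "x")
        assert a == b

    def test_every_generated_case_is_valid_and_conforming(self, small_cohort):
        for case in small_cohort:
            assert validate(case).ok
            assert segment(case).conforming

    def test_exactly_one_final_diagnosis(self, small_cohort):
        for case in small_cohort[:100]:
            finals = [o for o in case.options if o.outcome is Outcome.FINAL]
            assert len(finals) == 1

    def test_trajectories_are_monotone_between_endpoints(self, small_cohort):
        for case in small_cohort[:100]:
            for option in case.options:
                levels = [lvl for _, lvl in trajectory(case, option.option_id)]
                diffs = np.diff(levels)
                assert (diffs >= 0).all() or (diffs <= 0).all()

    def test_excluded_options_end_with_exclusion_flag(self, small_cohort):
        from dpmkit.core import ratings_for

        for case in small_cohort[:100]:
            for option in case.options:
                ratings = ratings_for(case, option.option_id)
                if option.outcome is Outcome.EXCLUDED:
                    assert ratings[-1].is_exclusion
                else:
                    assert not any(r.is_exclusion for r in ratings)


class TestCohortCalibration:
    """Law-of-large-numbers recovery of the configured parameters.

    Uses the session cohort (n = 300) with 4-SE bands; the stricter
    3-SE checks at n = 5000 live in the acceptance suite.
    """

    def test_empty_cohort(self, default_config):
        cases, prov = generate_cohort(dataclasses.replace(default_config, n_cases=0))
        assert cases == [] and prov["n_cases"] == 0

    def test_cohort_is_reproducible_and_order_independent(self, default_config):
        cfg = dataclasses.replace(default_config, n_cases=10)
        a, _ = generate_cohort(cfg, seed=42)
        b, _ = generate_cohort(cfg, seed=42)
        assert a == b
        # a case's structure depends only on (seed, index), not on cohort size
        wider, _ = generate_cohort(dataclasses.replace(cfg, n_cases=20), seed=42)
        assert [c.units for c in wider[:10]] == [c.units for c in a]

    def test_count_means_recovered(self, small_cohort, default_config):
        n = len(small_cohort)
        sums = [case_summary(c) for c in small_cohort]
        for metric, spec in [
            ("n_options", default_config.options),
            ("n_cues", default_config.cues),
        ]:
            values = [getattr(s, metric) for s in sums]
            assert abs(np.mean(values) - spec.mean) < 4 * spec.sd / np.sqrt(n)

    def test_structural_proportions_recovered(self, small_cohort, default_config):
        n = len(small_cohort)
        sums = [case_summary(c) for c in small_cohort]
        checks = [
            (np.mean([s.final_in_phase1 for s in sums]), default_config.p_final_in_phase1),
            (np.mean([s.options_added_phase2 > 0 for s in sums]), default_config.p_phase2_addition),
            (np.mean([c.metadata.time_pressure is TriState.YES for c in small_cohort]), 0.20),
        ]
        for observed, target in checks:
            assert abs(observed - target) < 4 * np.sqrt(target * (1 - target) / n)

    def test_endpoint_means_recovered(self, small_cohort, default_config):
        sums = [case_summary(c) for c in small_cohort]
        finals = [lvl for s in sums for lvl in s.final_terminal_levels]
        excluded = [lvl for s in sums for lvl in s.excluded_terminal_levels]
        assert abs(np.mean(finals) - 3.56) < 4 * 0.8 / np.sqrt(len(finals))
        assert abs(np.mean(excluded) + 2.50) < 4 * 2.2 / np.sqrt(len(excluded))
        assert np.mean([lvl == 4 for lvl in finals]) == pytest.approx(0.67, abs=4 * 0.47 / np.sqrt(len(finals)))

    def test_covariate_correlations_induced(self, default_config):
        import scipy.stats

        cfg = dataclasses.replace(default_config, n_cases=2000)
        cases, _ = generate_cohort(cfg, seed=314159)
        exp = np.array([c.metadata.experience_months for c in cases], float)
        p2 = np.array([phase_composition(c, segment(c)).phase2_cues for c in cases], float)
        assert np.corrcoef(exp, p2)[0, 1] == pytest.approx(-0.35, abs=0.05)
        sims = np.array([c.metadata.similarity or 0 for c in cases], float)
        mask = np.array([c.metadata.case_experience is TriState.YES for c in cases])
        conf = np.array([terminal_confidence(c, c.final_option_ids()[0]).value for c in cases], float)
        rs = scipy.stats.spearmanr(sims[mask], conf[mask]).statistic
        assert rs == pytest.approx(0.31, abs=0.05)
        # experience marginal untouched by the reordering
        assert exp.min() >= 23 and exp.max() <= 69
        assert abs(exp.mean() - 41) < 4 * 11 / np.sqrt(len(exp))


class TestRaterPairs:
    def test_discrepancy_profile(self, small_cohort):
        from dpmkit.concordance import concordance_rate, confidence_agreement

        rng = np.random.default_rng(8)
        pairs = generate_rater_pairs(small_cohort, rng)
        assert len(pairs) == len(small_cohort)
        summary = confidence_agreement(pairs)
        n = summary.n
        assert summary.perfect_match_pct / 100 == pytest.approx(0.333, abs=4 * 0.48 / np.sqrt(n))
        assert summary.max_discrepancy <= 2
        assert summary.expert_underconfident_pct > summary.expert_overconfident_pct
        assert concordance_rate(pairs) == pytest.approx(51 / 55, abs=4 * 0.27 / np.sqrt(n))
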