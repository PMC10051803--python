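"""Cohort generator: sampler marginals, truncation, device-usage model,
determinism, and the shipped calibration."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from mdsc import (
    ConfigurationError,
    default_config,
    generate_cohort,
    load_config,
    min_count_filter,
    packaged_default_config,
    sample_devices,
    sample_gmfcs,
    sample_gmfm_given_gmfcs,
    sample_subtype_given_gmfcs,
    save_config,
    usage_probability,
)
from mdsc.cohort import SUBTYPES
from mdsc.simulate import DeviceProfile, config_to_dict


def _cfg(**overrides):
    cfg = default_config(n_patients=overrides.pop("n_patients", 100), seed=0)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


class TestGmfcsSampler:
    def test_frequencies_match_study_proportions(self):
        cfg = _cfg()
        draws = sample_gmfcs(cfg, np.random.default_rng(1), size=100_000)
        freqs = np.bincount(draws, minlength=6)[1:] / len(draws)
        assert np.all(np.abs(freqs - np.asarray(cfg.gmfcs_probs)) < 0.005)

    def test_degenerate_distribution_is_constant(self):
        cfg = _cfg(gmfcs_probs=(1.0, 0.0, 0.0, 0.0, 0.0))
        draws = sample_gmfcs(cfg, np.random.default_rng(2), size=500)
        assert np.all(draws == 1)

    def test_uniform_distribution_is_symmetric(self):
        cfg = _cfg(gmfcs_probs=(0.2,) * 5)
        draws = sample_gmfcs(cfg, np.random.default_rng(3), size=50_000)
        freqs = np.bincount(draws, minlength=6)[1:] / len(draws)
        assert np.all(np.abs(freqs - 0.2) < 0.006)

    def test_invalid_probability_vector_rejected(self):
        cfg = _cfg()
        cfg.gmfcs_probs = (0.5, 0.5, 0.5, 0.0, 0.0)
        with pytest.raises(ConfigurationError):
            sample_gmfcs(cfg, np.random.default_rng(0), size=10)


class TestSubtypeSampler:
    def test_level_v_row_frequencies(self):
        cfg = _cfg()
        draws = sample_subtype_given_gmfcs(5, cfg, np.random.default_rng(4), size=100_000)
        expected = np.asarray(cfg.subtype_probs_by_level[4])
        freqs = np.array([(draws == s).mean() for s in SUBTYPES])
        assert np.all(np.abs(freqs - expected) < 0.005)
        assert freqs[SUBTYPES.index("unilateral_spastic")] == 0.0

    def test_level_i_unilateral_share(self):
        cfg = _cfg()
        draws = sample_subtype_given_gmfcs(1, cfg, np.random.default_rng(5), size=100_000)
        share = (draws == "unilateral_spastic").mean()
        assert abs(share - 0.398 / 0.999) < 0.005

    def test_degenerate_row_is_constant(self):
        rows = list(_cfg().subtype_probs_by_level)
        rows[2] = (0.0, 0.0, 1.0, 0.0, 0.0)
        cfg = _cfg(subtype_probs_by_level=tuple(rows))
        draws = sample_subtype_given_gmfcs(3, cfg, np.random.default_rng(6), size=200)
        assert set(draws) == {"dyskinetic"}


class TestGmfmSampler:
    def test_scores_bounded_and_centered(self):
        cfg = _cfg()
        draws = sample_gmfm_given_gmfcs(1, cfg, np.random.default_rng(7), size=10_000)
        assert np.all((draws >= 0) & (draws <= 100))
        expected = truncnorm.mean((0 - 85) / 8, (100 - 85) / 8, loc=85, scale=8)
        assert abs(draws.mean() - expected) < 0.3

    def test_zero_sd_returns_level_mean(self):
        cfg = _cfg(gmfm_level_sd=0.0)
        assert sample_gmfm_given_gmfcs(3, cfg, np.random.default_rng(8)) == 50.0

    def test_left_truncation_matches_truncnorm_oracle(self):
        # level V: mean 15, sd 8 -> truncation at 0 shifts the mean up;
        # compare against the closed-form truncated-normal expectation
        cfg = _cfg()
        m, sd = 15.0, 8.0
        draws = sample_gmfm_given_gmfcs(5, cfg, np.random.default_rng(9), size=40_000)
        oracle = truncnorm.mean((0 - m) / sd, (100 - m) / sd, loc=m, scale=sd)
        assert oracle > m
        assert abs(draws.mean() - oracle) < 3 * sd / np.sqrt(len(draws))


class TestDeviceUsage:
    def test_certain_at_peak_with_unit_base_rate(self):
        profile = DeviceProfile("x", "X", base_rate=1.0, score_center=50.0, score_width=5.0)
        cfg = _cfg()
        cfg.device_profiles = [profile]
        rng = np.random.default_rng(10)
        assert all(sample_devices(50.0, cfg, rng) == {"x"} for _ in range(50))

    def test_zero_rate_never_used(self):
        # base_rate must be > 0 by the invariant; the operational floor is
        # a vanishing rate
        profile = DeviceProfile("x", "X", base_rate=1e-12, score_center=50.0, score_width=5.0)
        cfg = _cfg()
        cfg.device_profiles = [profile]
        rng = np.random.default_rng(11)
        assert all(sample_devices(50.0, cfg, rng) == frozenset() for _ in range(200))

    def test_usage_probability_unimodal_for_all_defaults(self):
        grid = np.linspace(0, 100, 401)
        for profile in default_config().device_profiles:
            p = usage_probability(grid, profile)
            signs = np.sign(np.diff(p))
            changes = np.count_nonzero(np.diff(signs[signs != 0]))
            assert changes <= 1, profile.code
            peak = grid[np.argmax(p)]
            assert abs(peak - np.clip(profile.score_center, 0, 100)) < 0.5


class TestGenerateCohort:
    def test_reproducible_given_seed(self):
        cfg = default_config(n_patients=300, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = generate_cohort(default_config(n_patients=300, seed=1))
        b = generate_cohort(default_config(n_patients=300, seed=2))
        assert not a.equals(b)

    def test_records_within_bounds(self, default_cohort):
        scores = default_cohort.gmfm66
        ages = np.array([r.age for r in default_cohort.records])
        assert np.all((scores >= 0) & (scores <= 100))
        assert np.all((ages >= 2.2) & (ages <= 25.5))

    def test_rejects_empty_cohort(self):
        with pytest.raises(ConfigurationError):
            default_config(n_patients=0)

    def test_most_frequent_devices_match_published_ordering(self, default_cohort):
        counts = {
            c: default_cohort.catalog.count(c) for c in default_cohort.catalog.codes
        }
        top2 = sorted(counts, key=counts.get, reverse=True)[:2]
        assert set(top2) == {"transtibial_orthosis", "active_wheelchair"}

    def test_device_user_mean_ordering_large_cohort(self):
        # calibration property: with n >= 10,000 the device-user mean
        # ranking reproduces the published ordering, therapy bike highest
        # and passive wheelchair lowest of the whole catalog
        cohort = generate_cohort(default_config(n_patients=20_000, seed=77))
        means = {}
        for code in cohort.catalog.codes:
            users = [r.gmfm66 for r in cohort.records if code in r.devices]
            means[code] = np.mean(users)
        assert (
            means["therapy_bike"]
            > means["shoe_insert"]
            > means["roller_board"]
            > means["passive_wheelchair"]
        )
        assert max(means, key=means.get) == "therapy_bike"
        assert min(means, key=means.get) == "passive_wheelchair"


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("gmfcs_probs", (0.3, 0.3, 0.3, 0.05, 0.1)),
            ("gmfm_level_means", (85.0, 65.0, 65.0, 35.0, 15.0)),
            ("age_range", (25.0, 2.0)),
            ("female_prob", 1.5),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        cfg = _cfg()
        setattr(cfg, field, value)
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_invalid_device_profile_rejected(self):
        cfg = _cfg()
        cfg.device_profiles = [DeviceProfile("x", "X", 0.0, 50.0, 5.0)]
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestConfigFiles:
    def test_packaged_default_matches_builtin_calibration(self):
        shipped = packaged_default_config()
        built = default_config()
        assert config_to_dict(shipped) == config_to_dict(built)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(n_patients=50, seed=9)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        again = load_config(path)
        assert config_to_dict(again) == config_to_dict(cfg)

    def test_shipped_config_drives_identical_cohorts(self):
        a = generate_cohort(default_config(n_patients=200, seed=3))
        cfg = packaged_default_config()
        cfg.n_patients, cfg.seed = 200, 3
        assert a.equals(generate_cohort(cfg))


def test_filtering_keeps_all_patients(default_cohort):
    filtered = min_count_filter(default_cohort, 5)
    assert len(filtered) == len(default_cohort)
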