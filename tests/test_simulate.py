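"""Synthetic cohort generator: calibration, windowing, determinism."""

import datetime as dt
import math

import numpy as np
import pytest

from heatvalid.codes import build_ahi_codeset, encounter_is_algorithm_positive
from heatvalid.simulate import (
    ConfigError,
    GeneratorConfig,
    generate_cohort,
    generate_temperature_series,
    read_encounters_csv,
    read_weather_csv,
    write_encounters_csv,
    write_weather_csv,
)


class TestTemperatureSeries:
    def test_one_day_per_calendar_day(self):
        days = generate_temperature_series(2016, 26.1, 5.7, seed=0)
        assert len(days) == 153  # May 1 .. Sep 30
        assert days[0].date == dt.date(2016, 5, 1)
        assert days[-1].date == dt.date(2016, 9, 30)
        assert len({d.date for d in days}) == 153

    def test_seed_determinism(self):
        a = generate_temperature_series(2014, 24.2, 6.1, seed=1)
        b = generate_temperature_series(2014, 24.2, 6.1, seed=1)
        assert a == b

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_median_and_iqr_near_targets(self, seed):
        """Location-scale calibration: sample median/IQR concentrate on targets."""
        temps = np.array([d.tmax_c for d in generate_temperature_series(2016, 26.1, 5.7, seed)])
        assert abs(np.median(temps) - 26.1) < 1.0
        q1, q3 = np.percentile(temps, [25, 75])
        assert abs((q3 - q1) - 5.7) < 1.5

    def test_nonpositive_iqr_rejected(self):
        with pytest.raises(ConfigError):
            generate_temperature_series(2016, 26.1, 0.0, seed=0)


class TestConfig:
    def test_unknown_year_without_temp_params(self):
        with pytest.raises(ConfigError, match="2031"):
            GeneratorConfig.from_dict({"years": [2031]})

    def test_probability_bounds_checked(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(p_true_ahi=1.5).validate()

    def test_empty_background_pool_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(background_code_pool=()).validate()

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="typo"):
            GeneratorConfig.from_dict({"typo": 1})


class TestCohort:
    def test_dates_in_window_and_no_empty_code_lists(self):
        cfg = GeneratorConfig(n_encounters=2000, seed=5)
        encounters, weather = generate_cohort(cfg)
        assert len(encounters) == 2000
        for e in encounters:
            assert 5 <= e.date.month <= 9
            assert e.date.year in cfg.years
            assert len(e.codes) >= 1
            assert e.sex in ("female", "male")
            assert 1 <= e.ctas <= 5
        assert len(weather) == 153 * len(set(cfg.years))

    def test_perfect_coding_limit(self, ahi):
        """With coding noise off, algorithm positivity equals latent truth."""
        cfg = GeneratorConfig(
            n_encounters=3000,
            p_true_ahi=0.05,
            p_algo_code_given_ahi=1.0,
            p_algo_code_given_not_ahi=0.0,
            seed=2,
        )
        encounters, _ = generate_cohort(cfg)
        assert any(e.latent_true_ahi for e in encounters)
        for e in encounters:
            assert encounter_is_algorithm_positive(ahi, e.codes) == e.latent_true_ahi

    def test_positivity_calibrated_to_published_rate(self, ahi):
        """Default parameters put algorithm positivity at ~0.06% of encounters."""
        target = 208 / 326702
        n = 300_000
        cfg = GeneratorConfig(n_encounters=n, seed=11)
        encounters, _ = generate_cohort(cfg)
        pos = sum(encounter_is_algorithm_positive(ahi, e.codes) for e in encounters)
        band = 3 * math.sqrt(target * (1 - target) / n)
        assert abs(pos / n - target) < band

    def test_latent_prevalence_calibration(self):
        cfg = GeneratorConfig(n_encounters=100_000, p_true_ahi=0.004, seed=3)
        encounters, _ = generate_cohort(cfg)
        freq = sum(e.latent_true_ahi for e in encounters) / len(encounters)
        band = 3 * math.sqrt(0.004 * 0.996 / 100_000)
        assert abs(freq - 0.004) < band

    def test_documentation_follows_latent_truth_by_default(self):
        """Defaults: gold conjuncts always documented for true AHI, exposure never otherwise."""
        cfg = GeneratorConfig(n_encounters=20_000, p_true_ahi=0.01, seed=9)
        encounters, _ = generate_cohort(cfg)
        for e in encounters:
            if e.latent_true_ahi:
                assert e.exposure_documented and len(e.complaints) >= 1
            else:
                assert not e.exposure_documented

    def test_csv_round_trip_and_byte_determinism(self, tmp_path):
        cfg = GeneratorConfig(n_encounters=500, seed=4)
        encounters, weather = generate_cohort(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_encounters_csv(encounters, p1)
        encounters2, weather2 = generate_cohort(cfg)
        write_encounters_csv(encounters2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert read_encounters_csv(p1) == encounters

        w1 = tmp_path / "w.csv"
        write_weather_csv(weather, w1)
        rt = read_weather_csv(w1)
        assert [w.date for w in rt] == [w.date for w in weather]
        assert np.allclose([w.tmax_c for w in rt], [w.tmax_c for w in weather], atol=5e-4)
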