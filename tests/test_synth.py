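"""Generator determinism, calibration milestones and recovery tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from clleach.errors import DomainError
from clleach.synth import (
    GeneratorConfig,
    exogenous_layer_fractions,
    generate_profile_timeseries,
    generate_rainfall,
    generate_trial,
    generate_yield,
    truth_concentration,
)
from clleach.yield_safety import DoseResponseModel, DoseResponseResults


class TestRainfall:
    def test_sums_to_season_total(self):
        for total in (340.0, 700.0):
            rain = generate_rainfall(GeneratorConfig(seed=3, season_rain_total=total))
            assert rain["rain_mm"].sum() == pytest.approx(total, rel=0.02)
            assert (rain["rain_mm"] >= 0).all()
            assert len(rain) == 130

    def test_deterministic_under_seed(self):
        a = generate_rainfall(GeneratorConfig(seed=5))
        b = generate_rainfall(GeneratorConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = generate_rainfall(GeneratorConfig(seed=6))
        assert not a["rain_mm"].equals(c["rain_mm"])

    def test_total_rescales_events_without_changing_count(self):
        dry = generate_rainfall(GeneratorConfig(seed=5, season_rain_total=340))
        wet = generate_rainfall(GeneratorConfig(seed=5, season_rain_total=700))
        assert (dry["rain_mm"] > 0).sum() == (wet["rain_mm"] > 0).sum()
        mask = dry["rain_mm"] > 0
        ratio = wet.loc[mask, "rain_mm"] / dry.loc[mask, "rain_mm"]
        assert ratio.min() == pytest.approx(ratio.max(), rel=1e-12)


class TestProfileTimeseries:
    def test_bit_identical_under_seed(self):
        cfg = GeneratorConfig(seed=11)
        pd.testing.assert_frame_equal(
            generate_profile_timeseries(cfg), generate_profile_timeseries(cfg)
        )

    def test_noiseless_observations_equal_truth(self, noiseless_config):
        obs = generate_profile_timeseries(noiseless_config)
        for _, row in obs.sample(20, random_state=0).iterrows():
            dose = {"CK": 0.0, "L": 37.5, "M": 75.0, "H": 112.5}[row["treatment"]]
            want = truth_concentration(
                noiseless_config, dose, row["cum_rain_mm"],
                int(row["layer_top_cm"] // 15),
            )
            assert row["cl_mgkg"] == pytest.approx(want, rel=1e-12)

    def test_control_is_background_only(self, noiseless_config):
        obs = generate_profile_timeseries(noiseless_config)
        ck = obs[obs["treatment"] == "CK"]
        for layer, bg in zip((0.0, 15.0, 30.0), noiseless_config.backgrounds):
            vals = ck.loc[ck["layer_top_cm"] == layer, "cl_mgkg"]
            assert len(vals) > 0
            np.testing.assert_allclose(vals, bg, rtol=1e-12)

    def test_sampling_beyond_season_rejected(self):
        cfg = GeneratorConfig(seed=1, sampling_das=(10, 200))
        with pytest.raises(DomainError):
            generate_profile_timeseries(cfg)


class TestCalibration:
    """The generating truth reproduces the trial's distribution milestones."""

    def test_early_season_dose_stays_in_plough_layer(self):
        # ~85% of the exogenous Cl still in 0-15 cm after 20 mm of rain
        f = exogenous_layer_fractions(20.0, "loam", 37.5)
        resident_share = f[0] / (1.0 - f[3])
        assert 0.80 <= resident_share <= 0.90

    def test_mid_season_bulge_in_root_zone(self):
        # at ~70 mm the 15-30 cm layer holds the largest exogenous share
        f = exogenous_layer_fractions(70.0, "loam", 37.5)
        shares = np.array(f[:3]) / (1.0 - f[3])
        assert shares.argmax() == 1
        assert 0.40 <= shares[1] <= 0.55

    def test_sandy_loam_migrates_faster_early(self):
        for rain in (45.0, 70.0, 100.0):
            assert (
                exogenous_layer_fractions(rain, "sandy_loam", 75.0)[3]
                > exogenous_layer_fractions(rain, "loam", 75.0)[3]
            )

    def test_textures_converge_at_high_rain(self):
        loam = exogenous_layer_fractions(300.0, "loam", 75.0)[3]
        sandy = exogenous_layer_fractions(300.0, "sandy_loam", 75.0)[3]
        assert abs(loam - sandy) < 0.02

    def test_leached_fraction_monotone_in_rain_and_dose(self):
        rains = np.linspace(10, 320, 32)
        leach = [exogenous_layer_fractions(r, "loam", 75.0)[3] for r in rains]
        assert all(b >= a for a, b in zip(leach, leach[1:]))
        assert (
            exogenous_layer_fractions(150.0, "loam", 112.5)[3]
            > exogenous_layer_fractions(150.0, "loam", 37.5)[3]
        )

    @pytest.mark.parametrize("texture", ["loam", "sandy_loam"])
    def test_treated_and_control_converge_at_270mm(self, texture):
        # 0-45 cm profile-mean difference below 5 mg/kg for every dose
        cfg = GeneratorConfig(seed=0, texture=texture, noise_sd=0.0)
        for dose in (37.5, 75.0, 112.5):
            diffs = [
                truth_concentration(cfg, dose, 270.0, layer)
                - truth_concentration(cfg, 0.0, 270.0, layer)
                for layer in range(3)
            ]
            assert np.mean(diffs) < 5.0


class TestYield:
    WORKED = DoseResponseResults(
        p2=-0.001, p1=0.05, p0=100.0, n=0, dose_min=0.0, dose_max=150.0
    )

    def test_noiseless_control_yield(self):
        cfg = GeneratorConfig(seed=2, yield_cv=0.0)
        table = generate_yield(cfg, self.WORKED, cv=0.0)
        ck = table.loc[table["dose"] == 0.0, "yield_t_ha"]
        np.testing.assert_allclose(ck, cfg.control_yield, rtol=1e-12)

    def test_noiseless_end_to_end_safe_range_recovery(self):
        cfg = GeneratorConfig(seed=2)
        table = generate_yield(cfg, self.WORKED, cv=0.0)
        rng = DoseResponseModel.from_yields(table).fit().safe_range()
        assert rng.dose_ry100 == pytest.approx(50.0, abs=1e-6)
        assert rng.dose_ry95 == pytest.approx(100.0, abs=1e-6)

    def test_noisy_optimum_within_20_percent(self):
        from clleach.synth import default_yield_curve

        truth = default_yield_curve("loam")
        recovered = []
        for seed in range(21):
            cfg = GeneratorConfig(
                seed=seed, cl_doses=(0.0, 25.0, 50.0, 75.0, 100.0, 125.0)
            )
            table = generate_yield(cfg, truth, cv=0.05)
            fit = DoseResponseModel.from_yields(table).fit()
            recovered.append(fit.optimum_dose)
        assert np.median(recovered) == pytest.approx(truth.optimum_dose, rel=0.20)

    def test_deterministic(self):
        cfg = GeneratorConfig(seed=13)
        pd.testing.assert_frame_equal(generate_yield(cfg), generate_yield(cfg))


def test_trial_bundle_is_deterministic():
    cfg = GeneratorConfig(seed=21)
    t1, t2 = generate_trial(cfg), generate_trial(cfg)
    pd.testing.assert_frame_equal(t1.observations, t2.observations)
    pd.testing.assert_frame_equal(t1.rainfall, t2.rainfall)
    pd.testing.assert_frame_equal(t1.yields, t2.yields)


def test_texture_switch_shares_conditions():
    cfg = GeneratorConfig(seed=21)
    sandy = dataclasses.replace(cfg, texture="sandy_loam")
    t = generate_trial(sandy)
    assert set(t.observations["texture"]) == {"sandy_loam"}
    assert t.truth.backgrounds == sandy.backgrounds
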