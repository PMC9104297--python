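import numpy as np
import pytest

from edasites.io import PipelineConfig, ValidationError
from edasites.preprocess import resample_signal
from edasites.quality import noise_power_fraction
from edasites.simulate import (
    SimulationConfig,
    SiteProfile,
    simulate_cohort,
    simulate_recording,
)


def one_site_config(**site_kw):
    defaults = dict(tonic_level_us=5.0, tonic_drift_sd=0.0, responsiveness=1.0,
                    walking_noise_sd=0.0, lift_artifact_rate=0.0,
                    lift_artifact_amp_us=0.0)
    defaults.update(site_kw)
    return SimulationConfig(
        n_subjects=1,
        site_profiles=[SiteProfile("finger", **defaults)],
        measurement_noise_sd_us=0.0,
        seed=11,
    )


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_subjects=2, seed=5)
        (r1, g1), (r2, g2) = simulate_recording(cfg, 1), simulate_recording(cfg, 1)
        assert np.array_equal(r1.samples, r2.samples)
        for site in r1.sites:
            assert np.array_equal(g1.event_times_s[site], g2.event_times_s[site])

    def test_cohort_matches_single_subject(self):
        cfg = SimulationConfig(n_subjects=1, seed=3)
        (rc, _), = simulate_cohort(cfg)
        rs, _ = simulate_recording(cfg, 0)
        assert np.array_equal(rc.samples, rs.samples)

    def test_cohort_default_size_and_reproducibility(self):
        cfg = SimulationConfig(seed=2)
        assert cfg.n_subjects == 23
        small = SimulationConfig(n_subjects=3, seed=2)
        c1 = simulate_cohort(small)
        c2 = simulate_cohort(small)
        for (r1, _), (r2, _) in zip(c1, c2):
            assert np.array_equal(r1.samples, r2.samples)
        # subjects are distinct realizations
        assert not np.array_equal(c1[0][0].samples, c1[1][0].samples)


class TestGroundTruth:
    def test_all_noise_off_gives_constant_tonic(self, quiet_sim_config):
        rec, gt = simulate_recording(quiet_sim_config, 0)
        for j, site in enumerate(rec.sites):
            level = quiet_sim_config.site_profiles[j].tonic_level_us
            assert np.allclose(rec.samples[:, j], level)
            assert gt.event_times_s[site].size == 0

    def test_component_sum_reconstructs_exactly_when_noise_free(self):
        cfg = one_site_config(tonic_drift_sd=0.01, walking_noise_sd=0.05,
                              lift_artifact_rate=2.0, lift_artifact_amp_us=1.0)
        rec, gt = simulate_recording(cfg, 0)
        assert np.allclose(rec.channel("finger"), gt.component_sum("finger"),
                           atol=1e-12)

    def test_residual_is_measurement_noise(self):
        cfg = SimulationConfig(
            n_subjects=1,
            stage_plan=[("baseline", 120.0)],
            site_profiles=[SiteProfile("finger", tonic_drift_sd=0.01)],
            measurement_noise_sd_us=0.05,
            seed=21,
        )
        rec, gt = simulate_recording(cfg, 0)
        resid = rec.channel("finger") - gt.component_sum("finger")
        n = resid.size
        se = 0.05 / np.sqrt(n)
        assert abs(resid.mean()) < 3 * se
        assert abs(resid.std() - 0.05) < 0.05 * 0.05

    def test_event_times_strictly_increasing(self):
        cfg = SimulationConfig(n_subjects=1, seed=13)
        _, gt = simulate_recording(cfg, 0)
        for site in gt.sites:
            t = gt.event_times_s[site]
            assert np.all(np.diff(t) > 0)


class TestEventStatistics:
    def test_baseline_event_count_matches_poisson_mean(self):
        # rate 3/min on a 120 s baseline stage -> mean 6 events
        cfg = SimulationConfig(
            n_subjects=1,
            stage_plan=[("baseline", 120.0)],
            scr_rate_baseline_per_min=3.0,
            site_profiles=[SiteProfile("finger", responsiveness=1.0)],
            seed=29,
        )
        counts = []
        for i in range(200):
            _, gt = simulate_recording(cfg, i)
            counts.append(gt.event_times_s["finger"].size)
        mean = np.mean(counts)
        se = np.sqrt(6.0 / 200)  # Poisson variance = mean
        assert abs(mean - 6.0) < 3 * se

    def test_stress_rate_multiplier_recovered(self):
        cfg = SimulationConfig(
            n_subjects=1,
            scr_rate_stress_multiplier=2.0,
            site_profiles=[SiteProfile("finger", responsiveness=1.0)],
            seed=31,
        )
        n_base = n_stress = 0
        for i in range(300):
            _, gt = simulate_recording(cfg, i)
            t = gt.event_times_s["finger"]
            n_base += np.sum((t >= 0) & (t < 120))
            n_stress += np.sum((t >= 120) & (t < 240))
        ratio = n_stress / n_base
        assert abs(ratio - 2.0) < 0.25

    def test_responsiveness_thins_events(self):
        full = one_site_config(responsiveness=1.0)
        half_cfg = SimulationConfig(
            n_subjects=1,
            site_profiles=[SiteProfile("finger", responsiveness=0.5)],
            measurement_noise_sd_us=0.0,
            seed=11,
        )
        n_full = sum(
            simulate_recording(full, i)[1].event_times_s["finger"].size
            for i in range(100)
        )
        n_half = sum(
            simulate_recording(half_cfg, i)[1].event_times_s["finger"].size
            for i in range(100)
        )
        assert 0.4 < n_half / n_full < 0.6


class TestArtifacts:
    def test_walking_noise_raises_pn_in_walking_stage(self):
        quiet = one_site_config(tonic_drift_sd=0.01)
        noisy = one_site_config(tonic_drift_sd=0.01, walking_noise_sd=0.1)
        cfg_q = PipelineConfig()
        pns = {}
        for name, c in [("quiet", quiet), ("noisy", noisy)]:
            rec, _ = simulate_recording(c, 0)
            x8 = resample_signal(rec.channel("finger"), c.fs_raw, 8.0)
            sl = {"baseline": slice(0, 960), "walking": slice(1920, 2880)}
            pns[name] = {
                k: noise_power_fraction(x8[s], 8.0, cfg_q).pn for k, s in sl.items()
            }
        assert pns["noisy"]["walking"] > pns["noisy"]["baseline"]
        assert pns["noisy"]["walking"] > pns["quiet"]["walking"]

    def test_lift_artifacts_confined_to_weightlifting(self):
        cfg = one_site_config(lift_artifact_rate=6.0, lift_artifact_amp_us=2.0)
        rec, gt = simulate_recording(cfg, 0)
        art = gt.artifact_traces["finger"]
        fs = cfg.fs_raw
        assert np.all(art[: int(360 * fs)] == 0)
        assert np.max(np.abs(art[int(360 * fs):])) > 1.0

    def test_empty_stage_plan_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(stage_plan=[])


class TestHydrationRamp:
    def test_ramped_responsiveness_increases_late_event_rate(self):
        base = SiteProfile("forehead", responsiveness=0.2, responsiveness_end=0.8)
        cfg = SimulationConfig(
            n_subjects=1,
            scr_rate_stress_multiplier=1.0,  # uniform rate across stages
            site_profiles=[base],
            seed=41,
        )
        early = late = 0
        for i in range(150):
            _, gt = simulate_recording(cfg, i)
            t = gt.event_times_s["forehead"]
            early += np.sum(t < 240)
            late += np.sum(t >= 240)
        assert late > 1.5 * early
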