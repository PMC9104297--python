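import numpy as np
import pytest
from scipy import stats as sstats

from edasites.io import PipelineConfig, ValidationError
from edasites.stats import (
    CorrelationEntry,
    compare_stages,
    correlation_summary,
    correlation_table,
    hydration_progression,
    normality_gate,
    pearson_r,
    roc_curve,
    significance_stars,
)


class TestPearson:
    def test_hand_computed_values(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCorrelationTable:
    def make_subjects(self, n=23, responsive=True, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            ref = np.cumsum(rng.normal(0, 1, 400))
            if responsive:
                other = ref + rng.normal(0, 0.3, 400)
            else:
                other = np.cumsum(rng.normal(0, 1, 400))
            out.append(
                {"subject_id": f"S{i}", "raw": {"finger": ref, "foot": other}}
            )
        return out

    def test_duplicate_of_reference_has_r_one(self):
        x = np.cumsum(np.random.default_rng(1).normal(0, 1, 300))
        subj = [{"subject_id": "S0", "raw": {"finger": x, "foot": x.copy()}}]
        entries = correlation_table(subj, components=("raw",))
        assert len(entries) == 1
        assert entries[0].r == pytest.approx(1.0)

    def test_unresponsive_drifting_site_decorrelated(self):
        # a site that shares no sudomotor events with the reference and
        # only drifts independently shows low within-subject correlation
        from edasites.preprocess import resample_signal
        from edasites.simulate import SimulationConfig, SiteProfile

        cfg = SimulationConfig(
            n_subjects=23,
            stage_plan=[("baseline", 120.0), ("scwt", 120.0)],
            site_profiles=[
                SiteProfile("finger", responsiveness=0.9, tonic_drift_sd=0.02),
                SiteProfile("dead", responsiveness=0.0, tonic_drift_sd=0.02),
            ],
            seed=19,
        )
        from edasites.simulate import simulate_cohort

        subjects = []
        for rec, _ in simulate_cohort(cfg):
            subjects.append(
                {
                    "subject_id": rec.subject_id,
                    "raw": {
                        site: resample_signal(rec.channel(site), cfg.fs_raw, 8.0)
                        for site in rec.sites
                    },
                }
            )
        entries = correlation_table(subjects, components=("raw",))
        assert np.mean(np.abs([e.r for e in entries])) < 0.3

    def test_summary_shape_mean_and_sd(self):
        entries = correlation_table(self.make_subjects(), components=("raw",))
        df = correlation_summary(entries)
        assert set(df.columns) >= {"site", "component", "mean_r", "sd_r", "n"}
        row = df[df.site == "foot"].iloc[0]
        assert row.n == 23
        assert row.mean_r > 0.9

    def test_missing_reference_site_skipped(self, caplog):
        subj = [{"subject_id": "S0", "raw": {"foot": np.arange(10.0)}}]
        entries = correlation_table(subj, components=("raw",))
        assert entries == []


class TestNormalityGate:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(42).normal(0, 1, 23)
        assert normality_gate(x).passed

    def test_two_point_mass_fails(self):
        x = np.array([0.0, 10.0] * 12)[:23]
        assert not normality_gate(x).passed

    def test_constant_sample_degenerate(self):
        gate = normality_gate(np.full(10, 3.0))
        assert not gate.passed and gate.degenerate


class TestCompareStages:
    def test_identical_groups_not_significant(self):
        x = np.random.default_rng(0).normal(6, 1, 23)
        res = compare_stages(x, x.copy())
        assert res.p_value > 0.9
        assert not res.significant

    def test_strong_effect_detected_with_direction(self):
        rng = np.random.default_rng(7)
        base = rng.normal(6, 1, 23)
        stress = rng.normal(12, 1, 23)
        res = compare_stages(base, stress)
        assert res.significant
        assert res.statistic > 0  # stress > baseline
        assert res.stat_name == "paired_t"

    def test_nonnormal_groups_use_rank_sum(self):
        rng = np.random.default_rng(3)
        base = np.repeat([0.0, 10.0], 12)[:23] + rng.normal(0, 1e-3, 23)
        stress = np.repeat([0.0, 10.0], 12)[:23] + rng.normal(0, 1e-3, 23)
        res = compare_stages(base, stress)
        assert res.stat_name == "rank_sum"

    def test_signed_rank_option(self):
        rng = np.random.default_rng(3)
        base = np.repeat([0.0, 10.0], 12)[:23] + rng.normal(0, 1e-3, 23)
        stress = base + rng.normal(0.5, 1e-3, 23)
        cfg = PipelineConfig(paired_fallback=True)
        res = compare_stages(base, stress, cfg)
        assert res.stat_name == "signed_rank"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError, match="paired"):
            compare_stages(np.ones(10), np.ones(11))

    def test_null_type_i_error_near_nominal(self):
        """Empirical rejection rate within [0.03, 0.07] at the 0.05 level."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            base = rng.normal(6, 1, 23)
            stress = rng.normal(6, 1, 23)
            if compare_stages(base, stress).significant:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_permutation_destroys_significance(self):
        rng = np.random.default_rng(11)
        base = rng.normal(6, 1, 23)
        stress = rng.normal(12, 1, 23)
        assert compare_stages(base, stress).significant
        pooled = np.concatenate([base, stress])
        pvals = []
        for _ in range(200):
            rng.shuffle(pooled)
            pvals.append(compare_stages(pooled[:23], pooled[23:]).p_value)
        assert np.median(pvals) > 0.2


class TestRoc:
    def test_perfect_separation(self):
        res = roc_curve([1, 2], [3, 4])
        assert res.auc == pytest.approx(1.0)

    def test_interleaved_concordant_pairs(self):
        # concordant pairs 3 of 4 -> AUC 0.75
        res = roc_curve([1, 3], [2, 4])
        assert res.auc == pytest.approx(0.75)

    def test_reversed_effect_reported_as_is(self):
        res = roc_curve([3, 4], [1, 2])
        assert res.auc == pytest.approx(0.0)

    def test_monotone_sweep(self):
        rng = np.random.default_rng(2)
        res = roc_curve(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)
        assert res.tpr[0] == res.fpr[0] == 0.0
        assert res.tpr[-1] == res.fpr[-1] == 1.0

    def test_null_auc_centred_on_half(self):
        rng = np.random.default_rng(5)
        aucs = [
            roc_curve(rng.normal(0, 1, 23), rng.normal(0, 1, 23)).auc
            for _ in range(500)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_normalized_mann_whitney_u(self):
        """AUC must equal U / (n1*n2) on random instances, ties included."""
        rng = np.random.default_rng(9)
        for _ in range(500):
            n1, n2 = rng.integers(3, 12, size=2)
            a = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            b = rng.integers(0, 6, size=n2).astype(float)
            auc = roc_curve(a, b).auc
            u = sstats.mannwhitneyu(b, a, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1.0], [2.0, 3.0])


class TestHydrationProgression:
    def entries(self, stage, rs):
        return [
            CorrelationEntry(f"S{i}", "forehead", "raw", stage, r)
            for i, r in enumerate(rs)
        ]

    def test_all_high_correlations_counted(self):
        by_stage = {s: self.entries(s, [0.9] * 23) for s in ("baseline", "scwt", "walking")}
        assert hydration_progression(by_stage) == {
            "baseline": 23, "scwt": 23, "walking": 23
        }

    def test_boundary_value_excluded(self):
        by_stage = {"baseline": self.entries("baseline", [0.5, 0.500001, 0.499])}
        assert hydration_progression(by_stage, cut=0.5) == {"baseline": 1}

    def test_missing_subject_excluded_everywhere(self):
        by_stage = {
            "baseline": self.entries("baseline", [0.9, 0.9, 0.9]),
            "scwt": self.entries("scwt", [0.9, 0.9]),
        }
        assert hydration_progression(by_stage) == {"baseline": 2, "scwt": 2}


def test_significance_stars_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.06) == ""
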