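"""Synthetic cohort generator: quantile calibration, default recipe
composition, determinism, parameter recovery, config perturbation."""

import math

import numpy as np
import pytest
from scipy import stats

from roma_dx import synth
from roma_dx.cohort import DiagnosisClass, FigoStage, Grade, HistologyGroup
from roma_dx.synth import (
    Z75,
    GeneratorConfig,
    calibrate_lognormal_from_quantiles,
    config_from_json,
    config_to_json,
    default_config,
    generate_cohort,
    perturb_config,
)


class TestCalibration:
    def test_degenerate_point_mass(self):
        spec = calibrate_lognormal_from_quantiles(1.0, 1.0, 1.0)
        assert (spec.mu, spec.sigma) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "median,q1,q3,mu,sigma",
        [
            # frozen direct formula evaluations
            (45.4, 35.6, 60.8, 3.8155121050473024, 0.3967770829419831),
            (1260.7, 790.6, 2905.1, 7.139422401237224, 0.964752200356293),
        ],
    )
    def test_frozen_reference_calibrations(self, median, q1, q3, mu, sigma):
        spec = calibrate_lognormal_from_quantiles(median, q1, q3)
        assert spec.mu == pytest.approx(mu, abs=1e-12)
        assert spec.sigma == pytest.approx(sigma, abs=1e-12)

    def test_round_trip_median_and_iqr_ratio(self):
        spec = calibrate_lognormal_from_quantiles(100.0, 40.0, 220.0)
        assert spec.median == pytest.approx(100.0)
        assert spec.iqr_ratio == pytest.approx(220.0 / 40.0)
        # iqr_ratio identity: exp(2 * z75 * sigma)
        assert spec.iqr_ratio == pytest.approx(math.exp(2 * Z75 * spec.sigma))

    def test_violated_ordering_rejected(self):
        with pytest.raises(ValueError):
            calibrate_lognormal_from_quantiles(10.0, 12.0, 20.0)
        with pytest.raises(ValueError):
            calibrate_lognormal_from_quantiles(10.0, 5.0, 8.0)

    def test_theoretical_quartiles_of_calibrated_lognormal(self):
        """The calibrated distribution's exact quartile ratio matches the
        input, and its exact quartiles match when the input quartiles are
        log-symmetric around the median."""
        spec = calibrate_lognormal_from_quantiles(50.0, 25.0, 100.0)  # log-symmetric
        dist = stats.lognorm(s=spec.sigma, scale=math.exp(spec.mu))
        assert dist.ppf(0.25) == pytest.approx(25.0, rel=1e-9)
        assert dist.ppf(0.75) == pytest.approx(100.0, rel=1e-9)


class TestDefaultConfig:
    def test_class_sizes(self):
        cfg = default_config()
        assert (cfg.n_benign, cfg.n_malignant) == (228, 161)

    def test_benign_mix_weights(self):
        cfg = default_config()
        w = {g.histology_group: g.weight for g in cfg.benign_groups}
        assert w[HistologyGroup.ENDOMETRIOSIS] == pytest.approx(66 / 228)
        assert w[HistologyGroup.CYSTADENOMA_FIBROMA] == pytest.approx(78 / 228)
        assert w[HistologyGroup.MATURE_TERATOMA] == pytest.approx(29 / 228)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_malignant_mix_weights(self):
        cfg = default_config()
        by_label = {g.label: g for g in cfg.malignant_groups}
        # stage III holds 66/131 of the EOC mass; EOC (plus folded NEOC) is 135/161
        assert by_label["EOC FIGO III"].weight == pytest.approx((66 / 131) * (135 / 161))
        assert by_label["metastatic"].weight == pytest.approx(26 / 161)
        assert sum(g.weight for g in cfg.malignant_groups) == pytest.approx(1.0)

    def test_marker_medians_embed_reference_values(self):
        cfg = default_config()
        pooled = next(g for g in cfg.benign_groups if g.histology_group is HistologyGroup.OTHER_BENIGN)
        assert math.exp(pooled.ca125.mu) == pytest.approx(12.8)
        assert math.exp(pooled.he4.mu) == pytest.approx(45.4)
        stage_iv = next(g for g in cfg.malignant_groups if g.figo_stage is FigoStage.IV)
        assert math.exp(stage_iv.ca125.mu) == pytest.approx(1260.7)

    def test_menopause_probabilities(self):
        cfg = default_config()
        assert cfg.benign_groups[0].menopause_post_prob == pytest.approx(86 / 228)
        assert cfg.malignant_groups[0].menopause_post_prob == pytest.approx(119 / 161)

    def test_provenance_strings_present(self):
        cfg = default_config()
        for g in cfg.benign_groups + cfg.malignant_groups:
            assert g.ca125.source and g.he4.source

    def test_json_round_trip(self, tmp_path):
        cfg = default_config(seed=3)
        path = tmp_path / "cfg.json"
        config_to_json(cfg, path)
        assert config_from_json(path) == cfg


class TestGeneration:
    def test_empty_cohort(self):
        cfg = perturb_config(default_config(), {"n_benign": 0, "n_malignant": 0})
        assert len(generate_cohort(cfg)) == 0

    def test_determinism_same_seed(self):
        c1 = generate_cohort(default_config(seed=11))
        c2 = generate_cohort(default_config(seed=11))
        assert c1.records == c2.records

    def test_different_seeds_differ(self):
        c1 = generate_cohort(default_config(seed=11))
        c2 = generate_cohort(default_config(seed=12))
        assert any(a.ca125 != b.ca125 for a, b in zip(c1, c2))

    def test_parameter_recovery_at_large_n(self):
        """Sample medians of a 200,000-subject single-group cohort recover
        the calibration targets within 1%; the sample IQR ratio recovers
        exp(2 z75 sigma) within 2%."""
        cfg = default_config(seed=5)
        pooled = next(
            g for g in cfg.benign_groups if g.histology_group is HistologyGroup.OTHER_BENIGN
        )
        import dataclasses

        solo = dataclasses.replace(pooled, weight=1.0)
        big = dataclasses.replace(
            cfg, n_benign=200_000, n_malignant=0, benign_groups=(solo,), seed=5
        )
        cohort = generate_cohort(big)
        he4 = np.array([r.he4 for r in cohort])
        assert np.median(he4) == pytest.approx(45.4, rel=0.01)
        q1, q3 = np.quantile(he4, [0.25, 0.75])
        assert q3 / q1 == pytest.approx(solo.he4.iqr_ratio, rel=0.02)

    def test_mixture_proportions_converge(self):
        cfg = perturb_config(default_config(seed=9), {"n_benign": 20_000, "n_malignant": 0})
        cohort = generate_cohort(cfg)
        frac_endo = np.mean(
            [r.pathology.histology_group is HistologyGroup.ENDOMETRIOSIS for r in cohort]
        )
        # binomial 4-sigma band around 66/228
        p = 66 / 228
        assert abs(frac_endo - p) < 4 * math.sqrt(p * (1 - p) / 20_000)

    @staticmethod
    def _single_group_cfg(rank_corr, seed=13, n=50_000):
        """One-component benign config: the copula correlation is a
        within-group property (pooling distinct groups distorts it)."""
        import dataclasses

        cfg = default_config(seed=seed)
        solo = dataclasses.replace(cfg.benign_groups[0], weight=1.0, rank_corr=rank_corr)
        return dataclasses.replace(
            cfg, n_benign=n, n_malignant=0, benign_groups=(solo,), seed=seed
        )

    def test_rank_correlation_honoured(self):
        cohort = generate_cohort(self._single_group_cfg(0.3))
        ca = np.array([r.ca125 for r in cohort])
        he = np.array([r.he4 for r in cohort])
        assert stats.spearmanr(ca, he).statistic == pytest.approx(0.3, abs=0.03)

    def test_zero_rank_corr_gives_independence(self):
        cohort = generate_cohort(self._single_group_cfg(0.0))
        ca = np.array([r.ca125 for r in cohort])
        he = np.array([r.he4 for r in cohort])
        assert stats.spearmanr(ca, he).statistic == pytest.approx(0.0, abs=0.02)

    def test_grades_restricted_to_eoc(self, default_cohort):
        for r in default_cohort:
            if r.pathology.histology_group is not HistologyGroup.EOC:
                assert r.pathology.grade is Grade.NOT_APPLICABLE
                assert r.pathology.figo_stage is FigoStage.NOT_APPLICABLE

    def test_borderline_only_in_early_stage(self, default_cohort):
        for r in default_cohort:
            if r.pathology.grade is Grade.BORDERLINE:
                assert r.pathology.figo_stage in (FigoStage.I, FigoStage.II)

    def test_ages_truncated_at_18(self, default_cohort):
        assert min(r.age for r in default_cohort) >= 18.0


class TestPerturb:
    def test_empty_overrides_is_identity(self):
        cfg = default_config(seed=2)
        assert perturb_config(cfg, {}) == cfg

    def test_original_untouched(self):
        cfg = default_config()
        perturb_config(cfg, {"n_benign": 10})
        assert cfg.n_benign == 228

    def test_size_override(self):
        cfg = perturb_config(default_config(), {"n_benign": 10})
        cohort = generate_cohort(cfg)
        assert cohort.counts_by_diagnosis()[DiagnosisClass.BENIGN] == 10

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown config field"):
            perturb_config(default_config(), {"n_bengin": 10})

    def test_invalid_weights_rejected(self):
        cfg = default_config()
        bad = list(cfg.benign_groups)
        import dataclasses

        bad[0] = dataclasses.replace(bad[0], weight=0.9)
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(
                n_benign=cfg.n_benign,
                n_malignant=cfg.n_malignant,
                benign_groups=tuple(bad),
                malignant_groups=cfg.malignant_groups,
            )
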