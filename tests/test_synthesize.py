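"""Synthetic-cohort generator: determinism, truncation, parameter recovery."""
import numpy as np
import pytest
from statsmodels.stats.power import TTestIndPower

from argmet import (
    EffectSpec,
    GroupSpec,
    BASELINE_GROUPS,
    INTERVENTION_ACTIVE,
    INTERVENTION_PLACEBO,
    compare_groups,
    compute_delta,
    delta_matrix,
    generate_cross_sectional,
    generate_intervention,
)

BASE = GroupSpec(label="long_covid", arm="active", n=10,
                 means=(200.0, 40.0, 120.0, 0.6, 0.13, 0.7),
                 sds=(70.0, 13.0, 45.0, 0.14, 0.05, 0.15))


class TestSpecs:
    def test_bad_correlation_rejected(self):
        C = np.eye(6)
        C[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            GroupSpec(label="control", n=5, means=BASE.means, sds=BASE.sds,
                      correlation=C)
        C = np.ones((6, 6))  # singular
        with pytest.raises(ValueError, match="positive definite"):
            GroupSpec(label="control", n=5, means=BASE.means, sds=BASE.sds,
                      correlation=C)

    def test_bad_sds_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GroupSpec(label="control", n=5, means=BASE.means,
                      sds=(1.0, 1.0, 1.0, 1.0, 1.0, 0.0))

    def test_bad_delta_corr_rejected(self):
        with pytest.raises(ValueError, match="corr"):
            EffectSpec(baseline=BASE, delta_means=(0.0,) * 6,
                       delta_sds=(1.0,) * 6, baseline_delta_corr=1.0)


class TestCrossSectional:
    def test_vanishing_sds_collapse_to_means(self):
        spec = GroupSpec(label="control", n=5, means=BASE.means,
                         sds=(1e-9,) * 6)
        X = generate_cross_sectional([spec], seed=0).matrix()
        np.testing.assert_allclose(X, np.tile(BASE.means, (5, 1)), rtol=1e-6)

    def test_seed_determinism(self):
        a = generate_cross_sectional(BASELINE_GROUPS, seed=42)
        b = generate_cross_sectional(BASELINE_GROUPS, seed=42)
        c = generate_cross_sectional(BASELINE_GROUPS, seed=43)
        assert np.array_equal(a.matrix(), b.matrix())
        assert not np.array_equal(a.matrix(), c.matrix())

    def test_group_sizes_and_labels(self, cohort57):
        assert len(cohort57) == 57
        assert len(cohort57.partition(group="control")) == 11
        assert (cohort57.matrix() > 0).all()

    def test_large_sample_parameter_recovery(self):
        # law-of-large-numbers oracle at 20x the study sizes: errors bounded
        # by 5 MC sigmas plus the (small) positivity-truncation bias
        mult = 20
        big = [GroupSpec(label=s.label, arm=s.arm, n=s.n * mult,
                         means=s.means, sds=s.sds) for s in BASELINE_GROUPS]
        tab = generate_cross_sectional(big, seed=0)
        for s in big:
            sub = tab.partition(group=s.label,
                                arm=s.arm if s.arm != "none" else None)
            X = sub.matrix()
            means = np.asarray(s.means)
            sds = np.asarray(s.sds)
            se_mean = sds / np.sqrt(s.n)
            se_sd = sds / np.sqrt(2 * s.n)
            bias = 0.015 * means  # worst-case truncation bias at these specs
            assert np.all(np.abs(X.mean(0) - means) < 5 * se_mean + bias)
            assert np.all(np.abs(X.std(0, ddof=1) - sds) < 5 * se_sd + 0.04 * sds)

    def test_supplied_correlation_is_realised(self):
        C = np.eye(6)
        C[3, 5] = C[5, 3] = 0.9  # ADMA-SDMA
        spec = GroupSpec(label="control", n=4000, means=BASE.means,
                         sds=BASE.sds, correlation=C)
        X = generate_cross_sectional([spec], seed=1).matrix()
        r = np.corrcoef(X[:, 3], X[:, 5])[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_lognormal_margins_match_moments(self):
        spec = GroupSpec(label="control", n=20000, means=BASE.means,
                         sds=BASE.sds, margins="lognormal")
        X = generate_cross_sectional([spec], seed=2).matrix()
        np.testing.assert_allclose(X.mean(0), BASE.means, rtol=0.03)
        np.testing.assert_allclose(X.std(0, ddof=1), BASE.sds, rtol=0.08)
        assert (X > 0).all()


class TestIntervention:
    def test_zero_effect_returns_baseline(self):
        spec = EffectSpec(baseline=BASE, delta_means=(0.0,) * 6,
                          delta_sds=(1e-12,) * 6)
        tab = generate_intervention(spec, spec, seed=0)
        base = tab.partition(timepoint="baseline")
        day = tab.partition(timepoint="day28")
        by_id = {r.subject_id: r for r in day}
        for rec in base:
            d = compute_delta(rec, by_id[rec.subject_id])
            np.testing.assert_allclose(d.metabolite_deltas, 0.0, atol=1e-9)
            np.testing.assert_allclose(d.index_log_ratios, 0.0, atol=1e-10)

    def test_paired_structure(self, paired_cohort):
        assert len(paired_cohort) == 92  # 46 subjects x 2 visits
        D, arms, _ = delta_matrix(paired_cohort)
        assert D.shape == (46, 6)
        assert (arms == "active").sum() == 23

    def test_delta_difference_recovery(self):
        # generator's own parameters: mean arginine delta difference is
        # 67.8 − 5.3 = 62.5 µM; 300 replicates pin the MC error down
        diffs = []
        for seed in range(300):
            tab = generate_intervention(INTERVENTION_ACTIVE, INTERVENTION_PLACEBO, seed)
            D, arms, _ = delta_matrix(tab)
            diffs.append(D[arms == "active", 0].mean()
                         - D[arms == "placebo", 0].mean())
        se = np.sqrt(90.6**2 / 23 + 81.7**2 / 23) / np.sqrt(300)
        assert np.mean(diffs) == pytest.approx(62.5, abs=4 * se)

    def test_rejection_power_matches_closed_form(self):
        # the t-test power oracle at d≈0.72, n=23/23 gives ~0.67; the observed
        # rejection rate of compare_groups on generated arginine deltas must
        # agree within binomial noise
        d = 62.5 / np.sqrt((90.6**2 + 81.7**2) / 2)
        expected = TTestIndPower().power(effect_size=d, nobs1=23, alpha=0.05)
        assert expected == pytest.approx(0.67, abs=0.02)
        reps = 400
        rej = 0
        for seed in range(reps):
            tab = generate_intervention(INTERVENTION_ACTIVE, INTERVENTION_PLACEBO,
                                        10_000 + seed)
            D, arms, _ = delta_matrix(tab)
            res = compare_groups(D[arms == "active", 0],
                                 D[arms == "placebo", 0])
            rej += res.p_value < 0.05
        phat = rej / reps
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(phat - expected) < 4 * se + 0.02

    def test_baseline_delta_correlation(self):
        spec = EffectSpec(baseline=GroupSpec(label="long_covid", arm="active",
                                             n=4000, means=BASE.means,
                                             sds=BASE.sds),
                          delta_means=(0.0,) * 6, delta_sds=(50.0,) * 6,
                          baseline_delta_corr=-0.5)
        tab = generate_intervention(spec, spec, seed=5)
        base = tab.partition(timepoint="baseline", arm="active").matrix()
        day = tab.partition(timepoint="day28", arm="active").matrix()
        r = np.corrcoef(base[:, 0], (day - base)[:, 0])[0, 1]
        assert r == pytest.approx(-0.5, abs=0.06)
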