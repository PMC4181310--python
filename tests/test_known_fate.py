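"""Known-fate likelihood, constraints, fitting, AICc and survival outputs."""

import numpy as np
import pytest

from fawnfate import (
    KnownFateModel,
    SimConfig,
    aicc,
    build_histories,
    enumerate_partitions,
    field_filter,
    make_occasion_map,
    parse_group_spec,
    pooled_structure,
    simulate_cohort,
    singleton_structure,
)
from fawnfate.encounter import CENSORED, DIED, SURVIVED, EncounterHistory


def hist(entry, exit_, fate, label="KA", n=2, aid="x"):
    return EncounterHistory(aid, label, n, entry, exit_, fate)


class TestGroupStructures:
    def test_parse_two_groups(self):
        s = parse_group_spec("KA=R,H", ["KA", "R", "H"])
        assert s.groups == (("KA", "R"), ("H",))
        assert s.partition == {"KA": 1, "R": 1, "H": 2}
        assert s.display == "{KA = R, H}"

    def test_parse_singletons_and_braces(self):
        s = parse_group_spec("{KA, B, H, S, HS}", ["KA", "B", "H", "S", "HS"])
        assert s.n_groups == 5

    @pytest.mark.parametrize(
        "spec, match",
        [
            ("KA=KA", "duplicate"),
            ("KA=Q", "unknown"),
            ("KA", "omits"),
            ("KA=,H", "empty"),
        ],
    )
    def test_parse_errors(self, spec, match):
        with pytest.raises(ValueError, match=match):
            parse_group_spec(spec, ["KA", "H"])

    @pytest.mark.parametrize("n, bell", [(1, 1), (2, 2), (3, 5), (4, 15), (5, 52)])
    def test_partition_counts_are_bell_numbers(self, n, bell):
        cohorts = [f"C{i}" for i in range(n)]
        parts = enumerate_partitions(cohorts)
        assert len(parts) == bell
        assert len({p.spec_string for p in parts}) == bell
        for p in parts:
            assert sorted(c for g in p.groups for c in g) == sorted(cohorts)


class TestLikelihood:
    def test_closed_form_value_at_logit_zero(self):
        # one cell: 3 exposures, 2 deaths -> -2(1 ln .5 + 2 ln .5) = 6 ln 2
        hists = [
            hist(1, 1, SURVIVED, n=1, aid="a"),
            hist(1, 1, DIED, n=1, aid="b"),
            hist(1, 1, DIED, n=1, aid="c"),
        ]
        m = KnownFateModel(hists, make_occasion_map(1, "daily"), "KA", "constant")
        assert m.neg2_log_likelihood(np.array([0.0])) == pytest.approx(6 * np.log(2))
        assert m.exposures.tolist() == [3.0] and m.deaths.tolist() == [2.0]

    def test_no_deaths_boundary_limit_is_zero(self):
        hists = [hist(1, 2, SURVIVED, aid=f"a{i}") for i in range(4)]
        m = KnownFateModel(hists, make_occasion_map(2, "daily"), "KA", "constant")
        assert m.neg2_log_likelihood(np.array([30.0])) == pytest.approx(0.0, abs=1e-10)
        res = m.fit()
        assert res.neg2loglik == 0.0
        assert res.boundary.tolist() == [True]
        assert res.interval_survival[0] == pytest.approx(1.0, abs=1e-6)

    def test_beta_length_validated(self):
        hists = [hist(1, 2, SURVIVED)]
        m = KnownFateModel(hists, make_occasion_map(2, "daily"), "KA", "daily")
        with pytest.raises(ValueError, match="length"):
            m.neg2_log_likelihood(np.zeros(5))


class TestFit:
    def exposures_5_deaths_2(self):
        return [
            hist(1, 2, SURVIVED, aid="s"),  # survives both days
            hist(1, 1, DIED, aid="d1"),  # dies day 1
            hist(1, 2, DIED, aid="d2"),  # dies day 2
        ]

    def test_constant_model_mle_matches_closed_form(self):
        m = KnownFateModel(
            self.exposures_5_deaths_2(), make_occasion_map(2, "daily"), "KA", "constant"
        )
        res = m.fit()
        assert res.interval_survival[0] == pytest.approx(0.6, abs=1e-6)

    def test_mle_matches_grid_search_oracle(self):
        # independent oracle: dense grid over S per cell (cells separate)
        hists = (
            self.exposures_5_deaths_2()
            + [hist(1, 2, SURVIVED, "B", aid=f"b{i}") for i in range(6)]
            + [hist(1, 1, DIED, "B", aid="bd")]
            + [hist(2, 2, DIED, "C", aid="cd"), hist(1, 2, SURVIVED, "C", aid="cs")]
        )
        occ = make_occasion_map(2, "daily")
        m = KnownFateModel(hists, occ, "KA,B,C", "constant")
        assert m.K == 3
        res = m.fit()
        grid = np.linspace(0.0005, 0.9995, 1999)
        for j in range(3):
            n, d = m.exposures[j], m.deaths[j]
            neg2 = -2 * ((n - d) * np.log(grid) + d * np.log(1 - grid))
            s_grid = grid[np.argmin(neg2)]
            assert res.interval_survival[j] == pytest.approx(s_grid, abs=1e-3)

    def test_saturated_cell_survival_equals_deaths_over_exposures(self, wtd_known_age):
        occ = make_occasion_map(30, "daily")
        hists = build_histories(wtd_known_age, None, occ)
        m = KnownFateModel(hists, occ, None, "daily")
        res = m.fit()
        ok = m.exposures > 0
        np.testing.assert_allclose(
            res.interval_survival[ok], m.survivals[ok] / m.exposures[ok], atol=1e-6
        )
        assert res.deviance == pytest.approx(0.0, abs=1e-6)

    def test_refining_structure_never_increases_neg2loglik(self, wtd_known_age):
        from fawnfate import lookup_model

        occ = make_occasion_map(30, "daily")
        hists = build_histories(wtd_known_age, None, occ)
        hists += build_histories(
            wtd_known_age, lookup_model("white-tailed deer", "Brinkman"), occ
        )
        cohorts = ["KA", "B"]
        pooled = KnownFateModel(hists, occ, pooled_structure(cohorts), "constant").fit()
        split = KnownFateModel(hists, occ, singleton_structure(cohorts), "constant").fit()
        weekly = KnownFateModel(hists, occ, pooled_structure(cohorts), "weekly").fit()
        daily = KnownFateModel(hists, occ, pooled_structure(cohorts), "daily").fit()
        assert split.neg2loglik <= pooled.neg2loglik + 1e-8
        assert weekly.neg2loglik <= pooled.neg2loglik + 1e-8
        assert daily.neg2loglik <= weekly.neg2loglik + 1e-8

    def test_structural_K_counts_groups_times_blocks(self):
        hists = [hist(1, 30, SURVIVED, label, n=30, aid=f"{label}{i}")
                 for label in ("KA", "B") for i in range(3)]
        occ = make_occasion_map(30, "daily")
        assert KnownFateModel(hists, occ, None, "weekly").K == 8
        assert KnownFateModel(hists, occ, None, "daily").K == 60
        assert KnownFateModel(hists, occ, None, "constant").K == 2

    def test_empty_cohort_dropped_with_warning(self):
        hists = [hist(1, 2, SURVIVED, "KA")]
        structure = singleton_structure(["KA", "B"])
        with pytest.warns(UserWarning, match="zero animals"):
            m = KnownFateModel(hists, make_occasion_map(2, "daily"), structure)
        assert m.groups.cohorts == ("KA",)

    def test_censored_animal_contributes_exposure_through_exit(self):
        hists = [hist(1, 2, CENSORED, n=3, aid="c"), hist(1, 3, SURVIVED, n=3, aid="s")]
        m = KnownFateModel(hists, make_occasion_map(3, "daily"), "KA", "daily")
        assert m.exposures.tolist() == [2.0, 2.0, 1.0]
        assert m.deaths.sum() == 0


class TestAicc:
    def test_closed_form(self):
        assert aicc(100, 3, 100) == pytest.approx(100 + 6 + 24 / 96)
        assert aicc(100, 0, 100) == 100

    def test_equal_K_differences_cancel_correction(self):
        d = aicc(110, 4, 200) - aicc(100, 4, 200)
        assert d == pytest.approx(10.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n_eff"):
            aicc(100, 10, 11)


class TestCumulativeSurvival:
    def test_constant_daily_closed_form(self):
        # 1 death in 100 animal-days -> S = 0.99; 30 occasions -> 0.99^30
        hists = [hist(1, 10, SURVIVED, n=30, aid=f"s{i}") for i in range(9)]
        hists += [hist(1, 10, DIED, n=30, aid="d")]
        occ = make_occasion_map(30, "daily")
        res = KnownFateModel(hists, occ, "KA", "constant").fit()
        assert res.interval_survival[0] == pytest.approx(0.99, abs=1e-6)
        cs = res.cumulative_survival("KA")
        assert cs.estimate == pytest.approx(0.99**30, abs=1e-4)
        assert 0 < cs.ci_low < cs.estimate < cs.ci_high < 1

    def test_single_occasion_cumulative_equals_interval(self):
        hists = [hist(1, 1, SURVIVED, n=1, aid=f"s{i}") for i in range(7)]
        hists += [hist(1, 1, DIED, n=1, aid=f"d{i}") for i in range(3)]
        res = KnownFateModel(hists, make_occasion_map(1, "daily"), "KA", "constant").fit()
        cs = res.cumulative_survival("KA")
        assert cs.estimate == pytest.approx(res.interval_survival[0])
        assert cs.se == pytest.approx(res.interval_survival_se[0], rel=1e-6)

    def test_cumulative_non_increasing_in_horizon(self, wtd_known_age):
        occ = make_occasion_map(120, "daily")
        hists = build_histories(wtd_known_age, None, occ)
        res = KnownFateModel(hists, occ, "KA", "weekly").fit()
        curve = res.survival_curve("KA")["estimate"].to_numpy()
        assert np.all(np.diff(curve) <= 1e-12)
        assert np.all((curve >= 0) & (curve <= 1))

    def test_unknown_group_rejected(self):
        hists = [hist(1, 2, SURVIVED)]
        res = KnownFateModel(hists, make_occasion_map(2, "daily"), "KA", "constant").fit()
        with pytest.raises(KeyError):
            res.cumulative_survival("Z")

    def test_ci_covers_truth_at_nominal_rate(self):
        # repeated simulation: the 95% CI for 30-day survival should cover
        # the true value close to 95% of the time
        true = 0.985**30
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimConfig(
                n_neonates=100, horizon=30, daily_hazard=np.full(30, 0.015),
                shed_probability=0.0, seed=1000 + rep,
            )
            records, _ = simulate_cohort(cfg)
            occ = make_occasion_map(30, "daily")
            hists = build_histories(field_filter(records), None, occ)
            res = KnownFateModel(hists, occ, "KA", "constant").fit()
            cs = res.cumulative_survival("KA")
            covered += cs.ci_low <= true <= cs.ci_high
        rate = covered / n_rep
        tol = 3 * np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(rate - 0.95) < tol


class TestBetaCI:
    def fitted(self):
        hists = [hist(1, 2, SURVIVED, aid=f"s{i}") for i in range(8)]
        hists += [hist(1, 1, DIED, aid="d")]
        return KnownFateModel(hists, make_occasion_map(2, "daily"), "KA", "constant").fit()

    def test_overlap_flags(self):
        res = self.fitted()
        res.params[:] = [2.0]
        res.bse[:] = [0.5]
        assert not res.beta_ci_overlaps_zero()[0]  # CI (1.02, 2.98)
        res.params[:] = [0.1]
        res.bse[:] = [1.0]
        assert res.beta_ci_overlaps_zero()[0]
        res.params[:] = [0.0]
        assert res.beta_ci_overlaps_zero()[0]

    def test_summary_renders(self):
        text = self.fitted().summary()
        assert "cumulative survival" in text
        assert "AICc" in text
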