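import numpy as np
import pytest

from trbdisorder.reference_io import ClinicalRecord
from trbdisorder.scoring import CaseScore
from trbdisorder.survival import (SurvivalAnalysisError, cox_fit, km_estimate,
                                  logrank, median_split, stratify_and_test,
                                  univariate_gate)


def scores(values: dict[str, float], parameter: str = "p") -> list[CaseScore]:
    return [CaseScore(cid, parameter, v, 1) for cid, v in values.items()]


def clinical(times, events, ids=None, **covs) -> list[ClinicalRecord]:
    ids = ids or [f"c{i}" for i in range(len(times))]
    return [
        ClinicalRecord(case_id=cid, os_months=float(t), event=int(e),
                       covariates={k: v[i] for k, v in covs.items()})
        for i, (cid, t, e) in enumerate(zip(ids, times, events))
    ]


class TestMedianSplit:
    @pytest.mark.parametrize("n, expected", [(64, (32, 32)), (53, (27, 26)),
                                             (2, (1, 1)), (5, (3, 2))])
    def test_group_sizes(self, n, expected):
        rng = np.random.default_rng(n)
        vals = {f"c{i:03d}": float(rng.uniform()) for i in range(n)}
        clin = clinical(np.ones(n), np.ones(n), ids=sorted(vals))
        cohort = median_split(scores(vals), clin, "p")
        assert (len(cohort.lower_group), len(cohort.upper_group)) == expected
        assert not set(cohort.lower_group) & set(cohort.upper_group)
        assert set(cohort.lower_group) | set(cohort.upper_group) == set(vals)
        assert max(v for v in (vals[c] for c in cohort.lower_group)) <= \
            min(vals[c] for c in cohort.upper_group)

    def test_ties_broken_by_case_id(self):
        clin = clinical([1, 2], [1, 1], ids=["b", "a"])
        cohort = median_split(scores({"a": 0.5, "b": 0.5}), clin, "p")
        assert cohort.lower_group == ["a"] and cohort.upper_group == ["b"]

    def test_cases_without_scores_are_excluded_and_logged(self):
        clin = clinical([1, 2, 3], [1, 1, 1], ids=["a", "b", "noreads"])
        cohort = median_split(scores({"a": 0.1, "b": 0.9}), clin, "p")
        assert cohort.excluded_without_score == ["noreads"]
        assert cohort.n == 2

    def test_fewer_than_two_cases_is_an_error(self):
        clin = clinical([1], [1], ids=["a"])
        with pytest.raises(SurvivalAnalysisError):
            median_split(scores({"a": 0.5}), clin, "p")


class TestKaplanMeier:
    def test_all_events_step_curve(self):
        # hand product-limit: S drops by 1/5 at each of five event times
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0])
        np.testing.assert_allclose(curve.times, [0, 1, 2, 3, 4, 5])
        assert curve.median_os == 3
        assert list(curve.at_risk[1:]) == [5, 4, 3, 2, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3, 7, 9], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert curve.median_os is None

    def test_tied_event_and_censoring(self):
        # both at risk at t=2, one death: S(2) = 0.5, the smallest time with
        # S <= 0.5, hence the median
        curve = km_estimate([2, 2], [1, 0])
        assert curve.survival[-1] == pytest.approx(0.5)
        assert curve.median_os == 2

    def test_curve_is_monotone_from_one(self):
        rng = np.random.default_rng(4)
        curve = km_estimate(rng.exponential(10, 40), rng.integers(0, 2, 40))
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)


def permutation_logrank_p(times, events, n_a, n_draws=10_000, seed=0):
    """Monte-Carlo permutation oracle: permute group labels, recompute the
    log-rank statistic, report the tail fraction."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    idx = np.arange(len(times))

    def chi2(a_mask):
        return logrank(times[a_mask], events[a_mask],
                       times[~a_mask], events[~a_mask]).chi_square

    base_mask = np.zeros(len(times), bool)
    base_mask[:n_a] = True
    observed = chi2(base_mask)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        mask = np.zeros(len(times), bool)
        mask[rng.choice(idx, size=n_a, replace=False)] = True
        hits += chi2(mask) >= observed - 1e-12
    return observed, hits / n_draws


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t, e = [1, 3, 5, 8], [1, 1, 0, 1]
        result = logrank(t, e, t, e)
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(10, 20), rng.exponential(20, 25)
        ea, eb = np.ones(20), np.ones(25)
        assert logrank(ta, ea, tb, eb).chi_square == \
            pytest.approx(logrank(tb, eb, ta, ea).chi_square)

    def test_agrees_with_permutation_oracle(self):
        # moderate group sizes, where the chi-square approximation holds
        rng = np.random.default_rng(10)
        times = np.concatenate([rng.exponential(10, 15), rng.exponential(22, 15)])
        events = np.ones(30, int)
        _, p_perm = permutation_logrank_p(times, events, n_a=15, n_draws=2000, seed=1)
        p_asym = logrank(times[:15], events[:15], times[15:], events[15:]).p_value
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 2000)
        assert abs(p_asym - p_perm) < 3 * mc_se + 0.02

    def test_no_events_flagged_undefined(self):
        result = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert not result.defined and np.isnan(result.p_value)


def partial_loglik(beta, times, events, x):
    """Breslow/Efron partial log-likelihood (tie-free data, so identical)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_coefficient_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([0, 1] * 10, float)
        times = rng.exponential(1 / np.exp(0.8 * x))
        events = np.ones(20, int)
        clin = clinical(times, events, group=list(x))
        fit = cox_fit(clin, ["group"])
        grid = np.linspace(-4, 4, 8001)
        ll = [partial_loglik(b, times, events, x) for b in grid]
        beta_oracle = grid[int(np.argmax(ll))]
        assert fit.effects["group"].coefficient == pytest.approx(beta_oracle, abs=1e-3)
        eff = fit.effects["group"]
        assert eff.ci_lower < eff.hazard_ratio < eff.ci_upper
        assert eff.hazard_ratio == pytest.approx(np.exp(eff.coefficient))

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(1, 30)
        clin = clinical(times, np.ones(30), flat=[0.0] * 30,
                        group=list(np.tile([0.0, 1.0], 15)))
        fit = cox_fit(clin, ["flat", "group"])
        assert fit.dropped == ["flat"]
        assert set(fit.effects) == {"group"}

    def test_all_constant_covariates_is_an_error(self):
        clin = clinical([1, 2, 3], [1, 1, 1], flat=[1.0, 1.0, 1.0])
        with pytest.raises(SurvivalAnalysisError):
            cox_fit(clin, ["flat"])

    def test_no_events_is_an_error(self):
        clin = clinical([1, 2], [0, 0], g=[0.0, 1.0])
        with pytest.raises(SurvivalAnalysisError, match="event"):
            cox_fit(clin, ["g"])

    def test_recovers_true_hazard_ratio_three(self):
        # binary exposure with hazard ratio 3, n = 200, ~10% censoring
        rng = np.random.default_rng(12)
        estimates = []
        for _ in range(200):
            x = np.array([0.0, 1.0] * 100)
            t = rng.exponential(1 / (0.05 * 3 ** x))
            c = rng.uniform(0, 135, size=200)  # ~10% censored overall
            times, events = np.minimum(t, c), (t <= c).astype(int)
            clin = clinical(times, events, group=list(x))
            estimates.append(cox_fit(clin, ["group"]).effects["group"].hazard_ratio)
        assert 2.5 <= float(np.median(estimates)) <= 3.6


class TestUnivariateGate:
    def test_admits_at_the_p_threshold(self):
        rng = np.random.default_rng(13)
        x_strong = np.array([0.0, 1.0] * 30)
        times = rng.exponential(1 / np.exp(1.5 * x_strong))
        noise = list(rng.normal(size=60))
        clin = clinical(times, np.ones(60), strong=list(x_strong), noise=noise)
        p_strong = cox_fit(clin, ["strong"]).effects["strong"].p_value
        p_noise = cox_fit(clin, ["noise"]).effects["noise"].p_value
        admitted = univariate_gate(clin, ["strong", "noise"])
        assert ("strong" in admitted) == (p_strong <= 0.1)
        assert ("noise" in admitted) == (p_noise <= 0.1)
        assert "strong" in admitted  # HR e^1.5 at n=60 is far below p=0.1


class TestStratifyAndTest:
    def test_report_is_consistent_with_components(self):
        rng = np.random.default_rng(14)
        n = 30
        vals = {f"c{i:02d}": float(rng.uniform()) for i in range(n)}
        times = rng.exponential(20, n)
        clin = clinical(times, np.ones(n), ids=sorted(vals))
        report = stratify_and_test(scores(vals), clin, "p")
        assert report.n_lower == 15 and report.n_upper == 15
        lr = logrank(*_group_arrays(vals, clin, lower=True),
                     *_group_arrays(vals, clin, lower=False))
        assert report.chi_square == pytest.approx(lr.chi_square)
        assert "uncorrected" in report.caveat


def _group_arrays(vals, clin, lower):
    ranked = sorted(vals, key=lambda c: (vals[c], c))
    half = len(ranked) // 2
    ids = set(ranked[:half] if lower else ranked[half:])
    recs = [r for r in clin if r.case_id in ids]
    return np.array([r.os_months for r in recs]), np.array([r.event for r in recs])
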