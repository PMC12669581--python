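"""Survival stage: truncation, log-rank, Cox partial likelihood, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from protlca import concordance, cox_fit, km_logrank, truncate_followup
from protlca.survival import truncate_outcome_table


class TestTruncation:
    @pytest.mark.parametrize(
        "t, e, exp_t, exp_e",
        [(5.0, 1, 3.0, 0), (2.0, 1, 2.0, 1), (3.0, 1, 3.0, 1), (4.0, 0, 3.0, 0)],
    )
    def test_censor_at_horizon_rule(self, t, e, exp_t, exp_e):
        tt, ee = truncate_followup([t], [e], horizon=3.0)
        assert tt[0] == exp_t and ee[0] == exp_e

    def test_table_truncation(self):
        df = pd.DataFrame({
            "time_major_cv": [1.0, 5.0], "event_major_cv": [1, 1],
            "time_cv_death": [4.0, 2.0], "event_cv_death": [0, 1],
        })
        out = truncate_outcome_table(df, 3.0)
        assert out["time_major_cv"].tolist() == [1.0, 3.0]
        assert out["event_major_cv"].tolist() == [1, 0]
        assert out["time_cv_death"].tolist() == [3.0, 2.0]

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            truncate_followup([1.0], [1], horizon=0.0)


def _logrank_oracle(time, event, groups):
    """Textbook observed-minus-expected log-rank chi-square for 2 groups."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    gs = np.unique(groups)
    O = np.zeros(2)
    E = np.zeros(2)
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        for i, g in enumerate(gs):
            n_g = (at_risk & (groups == g)).sum()
            d_g = ((time == t) & (event == 1) & (groups == g)).sum()
            O[i] += d_g
            E[i] += d * n_g / n
        n1 = (at_risk & (groups == gs[0])).sum()
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O[0] - E[0]) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array([1, 1, 1, 2, 2, 2])
        _, chi2, df, p = km_logrank(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        groups = np.array([1, 1, 1, 2, 2, 2])
        _, chi2, _, _ = km_logrank(time, event, groups)
        assert chi2 == pytest.approx(_logrank_oracle(time, event, groups), abs=1e-8)

    def test_power_on_separated_hazards(self):
        rng = np.random.default_rng(0)
        n = 1500
        groups = rng.integers(1, 3, size=n)
        rate = np.where(groups == 1, 0.2, 1.0)
        time = rng.exponential(1 / rate)
        event = np.ones(n, dtype=int)
        _, chi2, _, p = km_logrank(time, event, groups)
        assert p < 1e-6

    def test_km_non_increasing_and_empirical(self):
        time = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 1.0, 4.0, 6.0])
        event = np.ones(8, dtype=int)
        groups = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        curves, *_ = km_logrank(time, event, groups)
        for g, sf in curves.items():
            vals = sf.iloc[:, 0].to_numpy()
            assert np.all(np.diff(vals) <= 1e-12)
        # no censoring: KM equals the empirical survival at each event time
        sf1 = curves[1].iloc[:, 0]
        t1 = time[groups == 1]
        for t, s in sf1.items():
            assert s == pytest.approx((t1 > t).mean(), abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            km_logrank([1.0, 2.0], [1, 1], [1, 1])


class TestCox:
    def test_brute_force_partial_likelihood(self):
        """Single binary covariate, no ties: coef equals direct maximization."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            ll = 0.0
            for i in range(len(time)):
                if event[i]:
                    risk = time >= time[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        res = cox_fit(time, event, covariates=pd.DataFrame({"x": x}))
        opt = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert res.hazard_ratios.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-6)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(1)
        n = 300
        time = rng.exponential(1.0, size=n)
        event = (rng.random(n) < 0.7).astype(int)
        labels = rng.integers(1, 3, size=n)
        res = cox_fit(time, event, labels=labels, reference=1)
        row = res.hazard_ratios.loc["cluster_2"]
        assert row["ci_low"] <= 1.1 and row["ci_high"] >= 0.9

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            cox_fit([1.0, 2.0], [0, 0], covariates=pd.DataFrame({"x": [0.0, 1.0]}))

    def test_rank_deficient_rejected(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        X = pd.DataFrame({"a": [1.0, 0, 1, 0], "b": [2.0, 0, 2, 0]})
        with pytest.raises(ValueError, match="rank"):
            cox_fit(time, event, covariates=X)

    def test_per_sd_standardization(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.5 * x))
        event = np.ones(n, dtype=int)
        res = cox_fit(time, event, covariates=pd.DataFrame({"x": 10 * x}),
                      standardize=True)
        # per-SD coefficient is scale invariant
        res2 = cox_fit(time, event, covariates=pd.DataFrame({"x": x}),
                       standardize=True)
        assert res.hazard_ratios.loc["x", "coef"] == pytest.approx(
            res2.hazard_ratios.loc["x", "coef"], abs=1e-8
        )


def _concordance_oracle(time, event, risk):
    num = den = 0.0
    for i, j in itertools.combinations(range(len(time)), 2):
        ti, tj = time[i], time[j]
        if ti == tj:
            continue
        first, second = (i, j) if ti < tj else (j, i)
        if not event[first]:
            continue  # shorter time censored: unusable
        den += 1
        if risk[first] > risk[second]:
            num += 1
        elif risk[first] == risk[second]:
            num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance(time, event, risk) == 1.0

    def test_five_sample_fixture_matches_pair_enumeration(self):
        time = np.array([2.0, 4.0, 3.0, 5.0, 1.0])
        event = np.array([1, 0, 1, 1, 1])
        risk = np.array([0.8, 0.1, 0.5, 0.2, 0.9])
        assert concordance(time, event, risk) == pytest.approx(
            _concordance_oracle(time, event, risk), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(1, 50)
        event = (rng.random(50) < 0.8).astype(int)
        risk = rng.normal(size=50)
        c1 = concordance(time, event, risk)
        c2 = concordance(time, event, np.exp(2 * risk) + 5)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        n = 2000
        time = rng.exponential(1, n)
        event = np.ones(n, dtype=int)
        risk = rng.normal(size=n)
        assert concordance(time, event, risk) == pytest.approx(0.5, abs=0.02)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [0, 0], [0.1, 0.2])
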