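"""Birth-death-sampling likelihoods, preservation model test and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from ammodiv import bds, simulate


def ptimes(rows):
    return pd.DataFrame(rows, columns=["lineage", "ts", "te"])


class TestBDLoglik:
    def test_constant_rate_closed_form(self):
        times = ptimes([("a", 10.0, 0.0)])
        lam = bds.PiecewiseRates([400.0, 0.0], [0.1])
        mu = bds.PiecewiseRates([400.0, 0.0], [0.1])
        got = bds.bd_loglik(times, lam, mu)
        assert got == pytest.approx(2 * np.log(0.1) - 0.2 * 10, abs=1e-8)
        assert got == pytest.approx(-6.60517, abs=1e-5)

    def test_integral_invariant_under_rate_duration_swap(self):
        # doubling rates while halving the duration leaves rate*d unchanged
        lam1 = bds.PiecewiseRates([400.0, 0.0], [0.1])
        mu1 = bds.PiecewiseRates([400.0, 0.0], [0.1])
        lam2 = bds.PiecewiseRates([400.0, 0.0], [0.2])
        mu2 = bds.PiecewiseRates([400.0, 0.0], [0.2])
        ll1 = bds.bd_loglik(ptimes([("a", 10.0, 0.0)]), lam1, mu1)
        ll2 = bds.bd_loglik(ptimes([("a", 5.0, 0.0)]), lam2, mu2)
        # event terms differ by 2 ln 2; integral terms are identical
        assert ll2 - ll1 == pytest.approx(2 * np.log(2.0), abs=1e-10)

    def test_two_frame_rates_match_quadrature(self):
        bounds = [400.0, 80.0, 0.0]
        lam = bds.PiecewiseRates(bounds, [0.3, 0.12])
        mu = bds.PiecewiseRates(bounds, [0.05, 0.2])
        times = ptimes([("a", 95.0, 12.0), ("b", 83.0, 70.0)])
        got = bds.bd_loglik(times, lam, mu)

        def total(t):
            return lam.rate_at(t) + mu.rate_at(t)

        expected = 0.0
        for _, ts, te in times.itertuples(index=False):
            # quadrature split at the frame boundary (integrand discontinuity)
            for a, b in [(te, min(ts, 80.0)), (min(ts, 80.0), ts)]:
                if b > a:
                    grid = np.linspace(a + 1e-9, b - 1e-9, 100_001)
                    expected -= integrate.trapezoid(total(grid), grid)
            expected += np.log(lam.rate_at(ts)) + np.log(mu.rate_at(te))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_domain_errors(self):
        lam = bds.PiecewiseRates([100.0, 0.0], [0.1])
        with pytest.raises(ValueError):
            bds.bd_loglik(ptimes([("a", 150.0, 10.0)]), lam, lam)
        with pytest.raises(ValueError):
            bds.PiecewiseRates([100.0, 0.0], [-0.1])

    def test_extant_lineage_contributes_no_death_event(self):
        lam = bds.PiecewiseRates([400.0, 0.0], [0.1])
        mu = bds.PiecewiseRates([400.0, 0.0], [0.3])
        t_ext = ptimes([("a", 10.0, 0.0)]).assign(extant=[True])
        t_dead = ptimes([("a", 10.0, 0.0)]).assign(extant=[False])
        diff = bds.bd_loglik(t_dead, lam, mu) - bds.bd_loglik(t_ext, lam, mu)
        assert diff == pytest.approx(np.log(0.3), abs=1e-10)


class TestPreservationLoglik:
    def test_hpp_closed_form(self):
        model = bds.PreservationModel("HPP", [113.2, 66.0], [0.5])
        times = ptimes([("a", 76.0, 66.0)])  # duration 10
        ages = {"a": [75.0, 72.0, 68.0]}
        got = bds.preservation_loglik(ages, times, model)
        expected = 3 * np.log(0.5) - 5.0 - np.log(1 - np.exp(-5.0))
        assert got == pytest.approx(expected, abs=1e-8)
        assert got == pytest.approx(-7.07268, abs=1e-5)

    def test_tpp_with_equal_bins_collapses_to_hpp(self):
        hpp = bds.PreservationModel("HPP", [113.2, 66.0], [0.7])
        tpp = bds.PreservationModel(
            "TPP", simulate.DEFAULT_STAGE_BOUNDS, [0.7] * 7
        )
        times = ptimes([("a", 101.0, 69.5)])
        ages = {"a": [99.0, 93.0, 80.0, 71.0]}
        a = bds.preservation_loglik(ages, times, hpp)
        b = bds.preservation_loglik(ages, times, tpp)
        assert a == pytest.approx(b, abs=1e-10)

    def test_loglik_diverges_as_rate_vanishes(self):
        # with n >= 2 occurrences each extra event contributes ln q -> -inf
        times = ptimes([("a", 80.0, 70.0)])
        ages = {"a": [75.0, 73.0, 71.0]}
        vals = []
        for q in [0.2, 0.1, 0.01, 0.001]:  # below the MLE n/d = 0.3
            model = bds.PreservationModel("HPP", [113.2, 66.0], [q])
            vals.append(bds.preservation_loglik(ages, times, model))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_occurrence_outside_duration_rejected(self):
        model = bds.PreservationModel("HPP", [113.2, 66.0], [0.5])
        with pytest.raises(ValueError):
            bds.preservation_loglik({"a": [81.0]}, ptimes([("a", 80.0, 70.0)]), model)

    def test_nhpp_unsupported(self):
        with pytest.raises(bds.UnsupportedModelError):
            bds.PreservationModel("NHPP", [113.2, 66.0], [0.5])


class TestPreservationModelTest:
    def test_aic_arithmetic(self):
        table = bds.fit_preservation_ml(
            ["a"] * 3 + ["b"] * 3,
            [90.0, 85.0, 80.0, 75.0, 72.0, 70.0],
            simulate.DEFAULT_STAGE_BOUNDS,
        )
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(2 * row["k"] - 2 * row["lnL"])

    @pytest.mark.parametrize("varying", [False, True])
    def test_model_selection_recovers_generating_process(self, varying):
        """HPP data prefers HPP; 4-fold bin-varying data prefers TPP
        (each in >= 80% of simulations)."""
        bounds = simulate.DEFAULT_STAGE_BOUNDS
        wins = 0
        n_sim = 25
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            if varying:
                q_spec = (np.asarray(bounds), None)
                q_vals = np.array([0.5, 2.0, 0.5, 2.0, 0.5, 2.0, 0.5])
            else:
                q_vals = np.full(7, 1.0)
            lineages, ages = [], []
            for i in range(60):
                ts = rng.uniform(90.0, 113.0)
                te = max(ts - rng.exponential(8.0), 66.5)
                if ts - te < 1.0:
                    continue
                occ = []
                for b_hi, b_lo, qv in zip(bounds[:-1], bounds[1:], q_vals):
                    a, b = min(ts, b_hi), max(te, b_lo)
                    if a > b:
                        k = rng.poisson(qv * (a - b))
                        occ.extend(rng.uniform(b, a, k))
                if len(occ) >= 2:
                    lineages.extend([f"g{i}"] * len(occ))
                    ages.extend(occ)
            table = bds.fit_preservation_ml(lineages, ages, bounds)
            winner = table.loc[table["winner"], "model"].iloc[0]
            delta = abs(table["AIC"].iloc[0] - table["AIC"].iloc[1])
            if varying:
                wins += winner == "TPP"
            else:
                wins += winner == "HPP" or delta <= 2
        assert wins >= 0.8 * n_sim


class TestHPD:
    def test_uniform_grid_width(self):
        lo, hi = bds.hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94

    def test_identical_samples_zero_width(self):
        lo, hi = bds.hpd_interval([3.0] * 10, 0.5)
        assert lo == hi == 3.0

    def test_bimodal_anchors_on_denser_mode(self):
        rng = np.random.default_rng(7)
        samples = np.concatenate([rng.normal(0, 0.1, 900), rng.normal(10, 0.1, 100)])
        lo, hi = bds.hpd_interval(samples, 0.5)
        # exhaustive check against the sliding-window oracle
        s = np.sort(samples)
        m = int(np.ceil(0.5 * len(s)))
        widths = s[m - 1:] - s[: len(s) - m + 1]
        i = int(np.argmin(widths))
        assert (lo, hi) == (s[i], s[i + m - 1])
        assert hi < 1.0  # anchored on the dense mode at 0

    def test_invalid_prob(self):
        with pytest.raises(ValueError):
            bds.hpd_interval([1.0, 2.0], 1.5)


class TestCombineLogs:
    def _log(self, n, cols=("a", "b")):
        return pd.DataFrame({c: np.arange(n, dtype=float) for c in cols})

    def test_ten_percent_burnin(self):
        out = bds.combine_logs([self._log(100)])
        assert len(out) == 90

    def test_ten_replicates(self):
        out = bds.combine_logs([self._log(100) for _ in range(10)])
        assert len(out) == 900
        assert sorted(out["replicate"].unique()) == list(range(10))

    def test_zero_burnin_identity(self):
        log = self._log(37)
        out = bds.combine_logs([log], burnin_fraction=0.0)
        pd.testing.assert_frame_equal(out.drop(columns="replicate"), log)

    def test_schema_mismatch(self):
        with pytest.raises(ValueError):
            bds.combine_logs([self._log(10), self._log(10, cols=("a", "c"))])


def _chain_row(bounds, lam, mu, ts_te):
    row = {
        "lam_bounds": ";".join(map(str, bounds)),
        "lam_rates": ";".join(map(str, lam)),
        "mu_bounds": ";".join(map(str, bounds)),
        "mu_rates": ";".join(map(str, mu)),
    }
    for name, (ts, te) in ts_te.items():
        row[f"ts_{name}"] = ts
        row[f"te_{name}"] = te
    return row


class TestRTTAndDiversity:
    def test_grid_means_match_hand_computation(self):
        rows = [
            _chain_row([113.2, 90.0, 66.0], [0.1, 0.3], [0.2, 0.2], {"a": (100, 70)}),
            _chain_row([113.2, 66.0], [0.2], [0.1], {"a": (100, 70)}),
            _chain_row([113.2, 80.0, 66.0], [0.4, 0.2], [0.3, 0.1], {"a": (100, 70)}),
            _chain_row([113.2, 66.0], [0.1], [0.4], {"a": (100, 70)}),
        ]
        chain = pd.DataFrame(rows)
        rtt = bds.rates_through_time(chain, [95.0, 75.0])
        # at 95 Ma: lam frames 0.1, 0.2, 0.4, 0.1; at 75 Ma: 0.3, 0.2, 0.2, 0.1
        assert rtt.summary["lam_mean"].tolist() == pytest.approx([0.2, 0.2])
        assert rtt.summary["mu_mean"].tolist() == pytest.approx([0.25, 0.2])

    def test_no_shifts_gives_nonpositive_logbf(self):
        rows = [_chain_row([113.2, 66.0], [0.2], [0.1], {"a": (100, 70)})] * 5
        rtt = bds.rates_through_time(pd.DataFrame(rows), [90.0])
        assert (rtt.shift_support["logbf"] <= 0).all()

    def test_p_equal_prior_gives_zero_logbf(self):
        # construct samples where the shift frequency equals the prior prob
        w = 113.2 - 66.0
        p0 = 1 - np.exp(-1.0)
        n = 1000
        k = int(round(p0 * n))
        rows = [_chain_row([113.2, 90.0, 66.0], [0.1, 0.2], [0.1, 0.1],
                           {"a": (100, 70)})] * k
        rows += [_chain_row([113.2, 66.0], [0.1], [0.1], {"a": (100, 70)})] * (n - k)
        rtt = bds.rates_through_time(pd.DataFrame(rows), [90.0])
        lam_bf = rtt.shift_support.query("rate == 'lam'")["logbf"].iloc[0]
        assert abs(lam_bf) < 0.05

    def test_diversity_counting(self):
        rows = [_chain_row([113.2, 66.0], [0.1], [0.1],
                           {"a": (10.0, 4.0), "b": (7.0, 2.0)})]
        curve = bds.diversity_curve(pd.DataFrame(rows), step=0.5)
        s = curve.summary.set_index("age")["mean_richness"]
        assert s.loc[8.0] == 1
        assert s.loc[5.0] == 2
        assert s.loc[1.0] == 0

    def test_intervals_nested(self, rng):
        rows = []
        for _ in range(50):
            rows.append(_chain_row([113.2, 66.0], [0.1], [0.1],
                                   {"a": (rng.uniform(9, 11), rng.uniform(1, 3)),
                                    "b": (rng.uniform(6, 8), rng.uniform(0, 1))}))
        curve = bds.diversity_curve(pd.DataFrame(rows), step=0.5)
        s = curve.summary
        assert (s["lo_95"] <= s["lo_75"]).all()
        assert (s["hi_75"] <= s["hi_95"]).all()

    def test_always_present_lineage_has_zero_width_interval(self):
        rows = [_chain_row([113.2, 66.0], [0.1], [0.1], {"a": (9.0, 2.0)})] * 20
        curve = bds.diversity_curve(pd.DataFrame(rows), step=0.5)
        s = curve.summary.set_index("age")
        assert s.loc[5.0, "lo_95"] == s.loc[5.0, "hi_95"] == 1

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            bds.rates_through_time(pd.DataFrame(), [90.0])
        with pytest.raises(ValueError):
            bds.diversity_curve(pd.DataFrame({"ts_a": []}), step=0.5)
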