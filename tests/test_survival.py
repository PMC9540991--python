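import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import rangeshift as rs
from rangeshift.survival import FitError, fit_exponential_frailty


def intercept_only(times, events, species=None):
    return pd.DataFrame({
        "time": times,
        "event": events,
        "species_id": species if species is not None else ["a"] * len(times),
    })


class TestClosedForms:
    def test_all_events_at_t2_gives_log2(self):
        tab = intercept_only([2.0] * 8, [1] * 8)
        f = fit_exponential_frailty(tab, [], frailty=None)
        assert f.beta[0] == pytest.approx(np.log(2.0), abs=1e-10)
        assert rs.predict_mean_time(f, tab)[0] == pytest.approx(2.0, abs=1e-9)

    def test_censored_mixture_gives_total_time_over_events(self):
        # 5 events at t=1 plus 5 censored at t=3: exposure 20, events 5 -> mean 4
        tab = intercept_only([1.0] * 5 + [3.0] * 5, [1] * 5 + [0] * 5)
        f = fit_exponential_frailty(tab, [], frailty=None)
        assert f.beta[0] == pytest.approx(np.log(4.0), abs=1e-10)
        assert rs.predict_mean_time(f, tab.iloc[:1])[0] == pytest.approx(4.0, abs=1e-8)

    def test_rate_equals_events_over_exposure_generally(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3.0, 50)
        e = (rng.random(50) < 0.6).astype(int)
        tab = intercept_only(t, e)
        f = fit_exponential_frailty(tab, [], frailty=None)
        assert np.exp(-f.beta[0]) == pytest.approx(e.sum() / t.sum(), abs=1e-10)


class TestFitValidation:
    def test_zero_events_rejected(self):
        with pytest.raises(FitError):
            fit_exponential_frailty(intercept_only([1, 2, 3], [0, 0, 0]), [], frailty=None)

    def test_collinear_design_names_columns(self):
        tab = intercept_only([1.0] * 20, [1] * 20)
        tab["x1"] = np.arange(20.0)
        tab["x2"] = 2.0 * tab["x1"]
        with pytest.raises(FitError, match="x"):
            fit_exponential_frailty(tab, ["x1", "x2"], frailty=None)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(FitError):
            fit_exponential_frailty(intercept_only([0.0, 1.0], [1, 1]), [], frailty=None)

    def test_missing_covariate_in_prediction(self):
        tab = intercept_only([1.0] * 10, [1] * 10)
        tab["x"] = np.linspace(-1, 1, 10)
        f = fit_exponential_frailty(tab, ["x"], frailty=None)
        with pytest.raises(ValueError):
            rs.predict_mean_time(f, pd.DataFrame({"y": [1.0]}))


class TestProperties:
    def _sim_table(self, seed, n=800, beta1=0.8, frailty_sd=0.0, n_species=8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        sp = rng.integers(0, n_species, n)
        b = rng.normal(0, frailty_sd, n_species) if frailty_sd else np.zeros(n_species)
        mu = np.exp(1.0 + beta1 * x + b[sp])
        T = rng.exponential(mu)
        L = 27.0
        return pd.DataFrame({
            "time": np.minimum(T, L), "event": (T <= L).astype(int),
            "x": x, "species_id": [f"s{i}" for i in sp],
        })

    def test_loglik_never_below_null(self):
        tab = self._sim_table(1)
        null = fit_exponential_frailty(tab, [], frailty=None)
        full = fit_exponential_frailty(tab, ["x"], frailty=None)
        assert full.loglik >= null.loglik

    def test_time_rescaling_shifts_intercept_only(self):
        tab = self._sim_table(2)
        f1 = fit_exponential_frailty(tab, ["x"], frailty=None)
        tab2 = tab.copy()
        c = 7.5
        tab2["time"] = tab2["time"] * c
        f2 = fit_exponential_frailty(tab2, ["x"], frailty=None)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(np.log(c), abs=1e-8)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-8)

    def test_positive_coefficient_means_longer_predicted_times(self):
        tab = self._sim_table(3)
        f = fit_exponential_frailty(tab, ["x"], frailty=None)
        lo = rs.predict_mean_time(f, pd.DataFrame({"x": [0.0]}))[0]
        hi = rs.predict_mean_time(f, pd.DataFrame({"x": [1.0]}))[0]
        assert (hi > lo) == (f.beta[1] > 0)

    def test_hand_evaluated_prediction(self):
        f = rs.FitResult(
            terms=["x"], names=["Intercept", "x"], beta=np.array([1.0, 0.5]),
            se=np.ones(2), loglik=0.0, aic=0.0, frailty_model=None,
            frailty_var=0.0, frailties={}, n=0, n_events=0, converged=True,
            n_params=2,
        )
        pred = rs.predict_mean_time(f, pd.DataFrame({"x": [2.0]}))
        assert pred[0] == pytest.approx(np.exp(2.0), rel=1e-12)

    def test_gaussian_frailty_recovers_variance_scale(self):
        # with only 20 species the estimable quantity is the realized sample
        # variance of the frailties, not the population sigma^2
        rng = np.random.default_rng(4)
        n, n_species = 4000, 20
        x = rng.normal(size=n)
        sp = rng.integers(0, n_species, n)
        b = rng.normal(0, 0.7, n_species)
        T = rng.exponential(np.exp(1.0 + 0.8 * x + b[sp]))
        tab = pd.DataFrame({
            "time": np.minimum(T, 27.0), "event": (T <= 27.0).astype(int),
            "x": x, "species_id": [f"s{i}" for i in sp],
        })
        f = fit_exponential_frailty(tab, ["x"], frailty="gaussian")
        assert f.converged
        assert 0.5 * b.var() < f.frailty_var < 2.0 * b.var()
        assert f.beta[1] == pytest.approx(0.8, abs=0.12)
        # estimated frailties track the true ones
        bhat = np.array([f.frailties[f"s{i}"] for i in range(n_species)])
        assert np.corrcoef(b - b.mean(), bhat)[0, 1] > 0.9

    def test_gamma_frailty_close_to_gaussian_fit(self):
        tab = self._sim_table(5, n=2000, frailty_sd=0.5, n_species=12)
        fg = fit_exponential_frailty(tab, ["x"], frailty="gaussian")
        fm = fit_exponential_frailty(tab, ["x"], frailty="gamma")
        assert fm.beta[1] == pytest.approx(fg.beta[1], abs=0.05)

    def test_aic_falls_when_true_covariate_added(self):
        wins = 0
        for rep in range(40):
            tab = self._sim_table(100 + rep, n=2000, beta1=0.5)
            base = fit_exponential_frailty(tab, [], frailty=None)
            full = fit_exponential_frailty(tab, ["x"], frailty=None)
            wins += full.aic < base.aic
        assert wins >= 38  # >= 95% of replicates


class TestInteractionTerms:
    def test_conditional_slopes_partition_the_effect(self):
        rng = np.random.default_rng(8)
        n = 3000
        flag = (rng.random(n) < 0.5).astype(float)
        x = rng.normal(size=n)
        mu = np.exp(1.0 + (0.8 * flag + (-0.3) * (1 - flag)) * x)
        T = rng.exponential(mu)
        tab = pd.DataFrame({
            "time": T, "event": 1, "flag": flag, "x": x,
            "species_id": "a",
        })
        f = fit_exponential_frailty(tab, ["flag", "flag:x", "!flag:x"], frailty=None)
        c = f.coef
        assert c["flag:x"] == pytest.approx(0.8, abs=0.1)
        assert c["!flag:x"] == pytest.approx(-0.3, abs=0.1)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstSurvreg:
    """Independent oracle: R survival::survreg, exponential distribution."""

    def test_coefficients_match_survreg(self, tmp_path):
        rng = np.random.default_rng(11)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.random(n)
        mu = np.exp(0.5 + 0.9 * x1 - 0.6 * x2)
        T = rng.exponential(mu)
        L = 8.0
        tab = pd.DataFrame({
            "time": np.minimum(T, L), "event": (T <= L).astype(int),
            "x1": x1, "x2": x2, "species_id": "a",
        })
        csv = tmp_path / "surv.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(survival))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- survreg(Surv(time, event) ~ x1 + x2, data = d, dist = 'exponential')\n"
            "cat(coef(m), sqrt(diag(vcov(m))), logLik(m), sep = '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_coef, r_se, r_ll = vals[:3], vals[3:6], vals[6]

        f = fit_exponential_frailty(tab, ["x1", "x2"], frailty=None)
        np.testing.assert_allclose(f.beta, r_coef, atol=1e-5)
        np.testing.assert_allclose(f.se, r_se, atol=1e-4)
        assert f.loglik == pytest.approx(r_ll, abs=1e-5)


class TestObservedCurve:
    def test_no_events_gives_flat_zero(self):
        tab = intercept_only([3.0, 5.0, 7.0], [0, 0, 0])
        curve = rs.observed_survival_curve(tab)
        assert (curve["cum_colonised"] == 0.0).all()

    def test_all_colonised_in_year_one(self):
        tab = intercept_only([1.0] * 10, [1] * 10)
        curve = rs.observed_survival_curve(tab)
        assert curve.loc[curve.year == 1, "cum_colonised"].item() == pytest.approx(1.0)

    def test_hand_computed_life_table(self):
        # events at years 1 and 2, one censored after year 1, one after year 3
        tab = intercept_only([1.0, 2.0, 1.0, 3.0], [1, 1, 0, 0])
        curve = rs.observed_survival_curve(tab)
        h1 = curve.loc[curve.year == 1, "hazard"].item()
        h2 = curve.loc[curve.year == 2, "hazard"].item()
        c2 = curve.loc[curve.year == 2, "cum_colonised"].item()
        assert h1 == pytest.approx(0.25)
        assert h2 == pytest.approx(0.5)
        assert c2 == pytest.approx(0.625)

    def test_tercile_grouping_returns_three_curves(self):
        rng = np.random.default_rng(12)
        tab = intercept_only(rng.uniform(0.5, 10, 300), rng.integers(0, 2, 300))
        tab["cov"] = rng.normal(size=300)
        curve = rs.observed_survival_curve(tab, group_col="cov")
        assert curve["group"].nunique() == 3
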