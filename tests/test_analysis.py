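"""Dataset assembly, quintile tabulation and regression tests.

The regression oracle is an independent likelihood maximisation with
scipy.optimize (Nelder-Mead refinement of a BFGS solution on the exact
log-likelihood), so the GLM path is checked against a second route.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from traffex.analysis import (
    METRICS,
    build_dataset,
    fit_logistic,
    fit_poisson,
    floor_positive,
    population_margins,
    quintile_summary,
    ratio_per_10pct,
    report,
)


def toy_inputs(n=12, seed=0):
    rng = np.random.default_rng(seed)
    pid = [f"p{i}" for i in range(n)]
    persons = pd.DataFrame(
        {
            "person_id": pid,
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(5, 70, n).round(1),
            "poverty_index": rng.uniform(0, 30, n).round(1),
        }
    )
    outcomes = pd.DataFrame(
        {
            "person_id": pid,
            "n_events": rng.poisson(1.0, n),
            "person_years": rng.integers(2, 11, n),
        }
    )
    outcomes["rate"] = outcomes["n_events"] / outcomes["person_years"]
    outcomes["any_event"] = outcomes["n_events"] > 0
    exposures = pd.DataFrame(
        {
            "person_id": pid,
            "vkt_250": rng.uniform(0, 4000, n),
            "vkt_500": rng.uniform(4000, 9000, n),
            "density": rng.uniform(0.05, 40, n),
        }
    )
    return outcomes, persons, exposures


class TestBuildDataset:
    def test_row_count_preserved_when_keys_align(self):
        ds, dropped = build_dataset(*toy_inputs())
        assert len(ds) == 12 and dropped == 0
        assert (ds["age_sq"] == ds["age"] ** 2).all()

    def test_missing_exposure_drops_row(self):
        outcomes, persons, exposures = toy_inputs()
        ds, dropped = build_dataset(outcomes, persons, exposures.iloc[1:])
        assert len(ds) == 11 and dropped == 1

    def test_log_floor_uses_half_minimum_positive(self):
        vals = np.array([0.0, 4.0, 8.0])
        floored = floor_positive(vals)
        np.testing.assert_allclose(floored, [2.0, 4.0, 8.0])
        outcomes, persons, exposures = toy_inputs(3)
        exposures["density"] = vals
        ds, _ = build_dataset(outcomes, persons, exposures)
        assert sorted(ds["log_density"])[0] == pytest.approx(np.log(2.0))

    def test_empty_join_raises(self):
        outcomes, persons, exposures = toy_inputs()
        exposures["person_id"] = "zz" + exposures["person_id"]
        with pytest.raises(ValueError):
            build_dataset(outcomes, persons, exposures)


class TestQuintileSummary:
    def frame(self, metric_vals, rates):
        return pd.DataFrame({"density": metric_vals, "rate": rates})

    def test_even_split_and_flat_rates(self):
        ds = self.frame(np.arange(1, 11), [0.1] * 10)
        t = quintile_summary(ds, "density").table
        assert list(t["n"]) == [2] * 5
        assert t["mean_rate"].tolist() == pytest.approx([0.1] * 5)

    def test_monotone_rates_give_monotone_bin_means(self):
        x = np.linspace(1, 100, 50)
        ds = self.frame(x, x / 100.0)
        means = quintile_summary(ds, "density").table["mean_rate"]
        assert (np.diff(means) > 0).all()

    def test_ties_assigned_to_lower_bin(self):
        vals = [1, 1, 1, 2, 3, 4, 5, 6, 7, 8]
        ds = self.frame(vals, np.arange(10) / 10)
        t = quintile_summary(ds, "density").table
        # all three 1s share the lowest bin
        assert t.loc[0, "n"] == 3
        assert int(t["n"].sum()) == 10

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ds = self.frame(rng.uniform(0, 10, 40), rng.uniform(0, 1, 40))
        a = quintile_summary(ds, "density").table
        b = quintile_summary(
            ds.sample(frac=1, random_state=1).reset_index(drop=True), "density"
        ).table
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            quintile_summary(self.frame([1, 1, 2, 2, 3], [0] * 5), "density")


def _nll_logistic(beta, X, y):
    eta = X @ beta
    return np.sum(np.logaddexp(0, eta)) - float(y @ eta)


def _nll_poisson(beta, X, y, off):
    eta = X @ beta + off
    return float(np.sum(np.exp(eta)) - y @ eta)


class TestRegression:
    def dataset(self, n=12, seed=4):
        outcomes, persons, exposures = toy_inputs(n, seed)
        ds, _ = build_dataset(outcomes, persons, exposures)
        return ds

    def design(self, ds, metric="density"):
        X = np.column_stack(
            [
                np.ones(len(ds)),
                ds["sex"], ds["age"], ds["age_sq"], ds["poverty_index"],
                ds[f"log_{metric}"],
            ]
        )
        return X

    def test_logistic_matches_brute_force_mle(self):
        # 12 rows with both outcome classes well mixed (finite MLE)
        ds = self.dataset(12, seed=5)
        res = fit_logistic(ds, "density")
        X = self.design(ds)
        y = ds["any_event"].to_numpy(float)
        opt = minimize(_nll_logistic, np.zeros(6), args=(X, y), method="BFGS")
        opt = minimize(_nll_logistic, opt.x, args=(X, y), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(
            res.params["estimate"].to_numpy(), opt.x, atol=1e-4
        )

    def test_poisson_matches_brute_force_mle(self):
        ds = self.dataset(30, seed=8)
        res = fit_poisson(ds, "density")
        X = self.design(ds)
        y = ds["n_events"].to_numpy(float)
        off = np.log(ds["person_years"].to_numpy(float))
        opt = minimize(_nll_poisson, np.zeros(6), args=(X, y, off), method="BFGS")
        opt = minimize(_nll_poisson, opt.x, args=(X, y, off), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(
            res.params["estimate"].to_numpy(), opt.x, atol=1e-4
        )

    def test_one_class_outcome_raises(self):
        ds = self.dataset(10)
        ds["any_event"] = True
        with pytest.raises(ValueError):
            fit_logistic(ds, "density")

    def test_all_zero_counts_raise(self):
        ds = self.dataset(10)
        ds["n_events"] = 0
        with pytest.raises(ValueError):
            fit_poisson(ds, "density")

    def test_equal_person_years_reduce_to_intercept_shift(self):
        ds = self.dataset(40, seed=6)
        ds["person_years"] = 5
        with_off = fit_poisson(ds, "density")
        # no-offset fit: give everyone one person-year
        ds2 = ds.copy()
        ds2["person_years"] = 1
        no_off = fit_poisson(ds2, "density")
        est_w = with_off.params["estimate"]
        est_n = no_off.params["estimate"]
        np.testing.assert_allclose(
            est_w.drop("const"), est_n.drop("const"), atol=1e-8
        )
        assert est_n["const"] - est_w["const"] == pytest.approx(np.log(5), abs=1e-8)

    def test_ci_brackets_estimate(self):
        ds = self.dataset(60, seed=9)
        for fit in (fit_logistic, fit_poisson):
            r = fit(ds, "vkt_500")
            assert (r.params["ci_lo"] <= r.params["estimate"]).all()
            assert (r.params["estimate"] <= r.params["ci_hi"]).all()


class TestRatioPer10Pct:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.0, 1.0), (np.log(2) / np.log(1.1), 2.0), (1.0, 1.1)],
    )
    def test_known_transformations(self, beta, expected):
        ds = TestRegression().dataset(40, seed=10)
        r = fit_poisson(ds, "density")
        r.params.loc["log_density", ["estimate", "ci_lo", "ci_hi"]] = beta
        r = ratio_per_10pct(r)
        assert r.ratio_per_10pct_ci[0] == pytest.approx(expected, rel=1e-12)

    def test_requires_log_metric(self):
        ds = TestRegression().dataset(40, seed=10)
        r = fit_poisson(ds, "density")
        r.log_metric = False
        with pytest.raises(RuntimeError):
            ratio_per_10pct(r)

    def test_invariant_to_metric_rescaling(self):
        outcomes, persons, exposures = toy_inputs(80, seed=12)
        ds1, _ = build_dataset(outcomes, persons, exposures)
        exposures2 = exposures.copy()
        exposures2["density"] *= 1000.0
        ds2, _ = build_dataset(outcomes, persons, exposures2)
        r1 = ratio_per_10pct(fit_poisson(ds1, "density"))
        r2 = ratio_per_10pct(fit_poisson(ds2, "density"))
        assert r1.ratio_per_10pct_ci == pytest.approx(r2.ratio_per_10pct_ci, rel=1e-8)
        # only the intercept moves
        np.testing.assert_allclose(
            r1.params["estimate"].drop("const"),
            r2.params["estimate"].drop("const"),
            atol=1e-8,
        )


class TestPopulationMargins:
    def test_percentages_from_counts(self):
        persons = pd.DataFrame(
            {
                "sex": ["male"] * 44 + ["female"] * 56,
                "age": [2.0] * 14 + [30.0] * 86,
                "poverty_index": [5.0] * 72 + [15.0] * 28,
            }
        )
        m = population_margins(persons).set_index(["characteristic", "category"])
        assert m.loc[("sex", "male"), "percent"] == pytest.approx(44.0)
        assert m.loc[("age", "0-4"), "percent"] == pytest.approx(14.0)
        assert m.loc[("poverty", "1-10"), "percent"] == pytest.approx(72.0)
        sex_counts = m.loc[("sex", "male"), "count"] + m.loc[("sex", "female"), "count"]
        assert sex_counts == m.loc[("total", "all"), "count"]


class TestReport:
    def test_blocks_figure_and_byte_identical_rerun(self, small_dataset, tmp_path):
        summaries = [quintile_summary(small_dataset, m) for m in METRICS]
        results = []
        for m in METRICS:
            results.append(ratio_per_10pct(fit_logistic(small_dataset, m)))
            results.append(ratio_per_10pct(fit_poisson(small_dataset, m)))
        payload = report(summaries, results, tmp_path / "a")
        assert len(payload["results"]) == 6
        report(summaries, results, tmp_path / "b")
        for name in ("results.json", "quintiles.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        assert (tmp_path / "a" / "fig_quintiles.png").stat().st_size > 0
        # round-trip through the JSON reader yields the same structure
        import json

        assert json.loads((tmp_path / "a" / "results.json").read_text()) == json.loads(
            json.dumps(payload)
        )
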