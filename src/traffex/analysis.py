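"""Exposure-response analysis: quintile tabulation and regression models.

The analysis dataset joins per-person outcomes, demographics and the three
traffic metrics, and adds natural-log-transformed metrics (zeros floored at
half the minimum positive observed value).  Two models are fitted per metric:

* logistic — any exacerbation (1) vs none (0) on sex, age, age^2, block-group
  poverty and the log metric;
* Poisson — the event count with log person-years as a fixed-coefficient
  offset (modelling the events/person-year rate) and the same covariates.

Because the traffic metric enters in natural log, the odds or rate ratio for
a 10% increase in traffic is exp(beta * ln 1.1); a per-10% ratio is invariant
to any positive rescaling of the raw metric.  Confidence intervals are Wald:
estimate +/- 1.96 standard errors, transformed with the estimate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("traffex")

__all__ = [
    "METRICS",
    "QuintileSummary",
    "RegressionResult",
    "floor_positive",
    "build_dataset",
    "quintile_summary",
    "fit_logistic",
    "fit_poisson",
    "ratio_per_10pct",
    "population_margins",
    "report",
]

METRICS = ("density", "vkt_250", "vkt_500")
COVARIATES = ("sex", "age", "age_sq", "poverty_index")
Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ContractError(RuntimeError):
    """An operation was applied outside its stated contract."""


def floor_positive(values: np.ndarray) -> np.ndarray:
    """Replace non-positive entries by half the minimum positive value.

    Deterministic and scale-covariant; raises if no positive value exists.
    """
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if len(pos) == 0:
        raise ValueError("cannot derive a log floor: no positive values")
    return np.where(values > 0, values, pos.min() / 2.0)


def build_dataset(
    outcomes: pd.DataFrame,
    persons: pd.DataFrame,
    exposures: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Inner-join outcomes, demographics and exposures into the model table.

    Adds ``sex`` coded male=1/female=0, ``age_sq`` = age^2, and
    ``log_<metric>`` columns with the half-minimum-positive floor applied to
    zeros.  Rows with any missing field are dropped (complete-case analysis)
    and the number dropped is returned alongside the dataset.
    """
    df = (
        outcomes.merge(
            persons[["person_id", "sex", "age", "poverty_index"]], on="person_id"
        )
        .merge(exposures[["person_id", *METRICS]], on="person_id")
    )
    if df.empty:
        raise ValueError("empty join: no person appears in all three inputs")
    n_before = max(len(outcomes), len(persons), len(exposures))
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("build_dataset: dropped %d incomplete rows", n_dropped)
    df = df.copy()
    df["sex"] = (df["sex"] == "male").astype(int) if df["sex"].dtype == object else df["sex"]
    df["age_sq"] = df["age"] ** 2
    for m in METRICS:
        df[f"log_{m}"] = np.log(floor_positive(df[m].to_numpy()))
    return df.reset_index(drop=True), n_dropped


# ---------------------------------------------------------------------------
# Quintile tabulation
# ---------------------------------------------------------------------------

@dataclass
class QuintileSummary:
    """Mean exacerbation rate within quintiles of one traffic metric.

    ``table`` has one row per quintile (1 = lowest traffic, 5 = highest) with
    the bin's value range, person count and mean events/person-year.
    """

    metric: str
    table: pd.DataFrame


def quintile_summary(dataset: pd.DataFrame, metric: str) -> QuintileSummary:
    """Partition persons into exposure quintiles and average the event rate.

    Bins are rank-based (sizes differ by at most one under distinct values);
    tied metric values are always assigned to the lower bin, so the bins
    partition the persons deterministically regardless of row order.
    """
    vals = dataset[metric].to_numpy(float)
    if len(np.unique(vals)) < 5:
        raise ValueError(f"metric {metric}: need >= 5 distinct values for quintiles")
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(len(vals), dtype=int)
    ranks[order] = np.arange(len(vals))
    bins = (ranks * 5) // len(vals)
    # ties: every occurrence of a value takes the lowest bin seen for it
    s = pd.Series(bins)
    low = s.groupby(vals).transform("min").to_numpy()
    bins = low
    rows = []
    for q in range(5):
        mask = bins == q
        sub = vals[mask]
        rows.append(
            {
                "quintile": q + 1,
                "lo": float(sub.min()) if mask.any() else math.nan,
                "hi": float(sub.max()) if mask.any() else math.nan,
                "n": int(mask.sum()),
                "mean_rate": float(dataset.loc[mask, "rate"].mean()) if mask.any() else math.nan,
            }
        )
    return QuintileSummary(metric=metric, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """A fitted logistic or Poisson model for one traffic metric.

    ``params`` indexes coefficient name -> (estimate, se, ci_lo, ci_hi) on
    the log-odds / log-rate scale.  ``ratio_per_unit_log`` is exp(beta) for
    the log-metric coefficient; after :func:`ratio_per_10pct` the per-10%
    ratio exp(beta ln 1.1) and its CI are filled in.
    """

    model: str  # "logistic" | "poisson"
    metric: str
    n: int
    params: pd.DataFrame
    log_metric: bool = True
    ratio_per_unit_log: tuple[float, float, float] | None = None
    ratio_per_10pct_ci: tuple[float, float, float] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def metric_term(self) -> str:
        return f"log_{self.metric}"


def _design(dataset: pd.DataFrame, metric: str) -> pd.DataFrame:
    X = dataset[[*COVARIATES, f"log_{metric}"]].astype(float)
    return sm.add_constant(X, has_constant="add")


def _wald_table(res) -> pd.DataFrame:
    est = res.params
    se = res.bse
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_lo": est - Z95 * se,
            "ci_hi": est + Z95 * se,
        }
    )


def _per_unit_ratio(tab: pd.DataFrame, term: str) -> tuple[float, float, float]:
    r = tab.loc[term]
    return (
        float(np.exp(r["estimate"])),
        float(np.exp(r["ci_lo"])),
        float(np.exp(r["ci_hi"])),
    )


def fit_logistic(dataset: pd.DataFrame, metric: str) -> RegressionResult:
    """Logistic regression of any-exacerbation on demographics + log metric.

    Maximum-likelihood fit with Wald standard errors; pairwise interaction
    terms are not included.  Raises on a one-class outcome or non-convergence.
    """
    y = dataset["any_event"].astype(int)
    if y.nunique() < 2:
        raise ValueError("logistic outcome has a single class; cannot fit")
    X = _design(dataset, metric)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError("logistic fit failed: non-finite standard errors "
                           "(possible separation)")
    tab = _wald_table(res)
    return RegressionResult(
        model="logistic",
        metric=metric,
        n=len(dataset),
        params=tab,
        ratio_per_unit_log=_per_unit_ratio(tab, f"log_{metric}"),
    )


def fit_poisson(dataset: pd.DataFrame, metric: str) -> RegressionResult:
    """Poisson regression of the event count with a log person-years offset.

    The offset (fixed coefficient 1 on ln person-years) makes the fitted
    linear predictor the log of the events/person-year rate.
    """
    y = dataset["n_events"].astype(int)
    if (y == 0).all():
        raise ValueError("all event counts are zero; degenerate Poisson outcome")
    if (dataset["person_years"] <= 0).any():
        raise ValueError("person_years must be positive for the rate offset")
    X = _design(dataset, metric)
    offset = np.log(dataset["person_years"].astype(float))
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError("poisson fit failed: non-finite standard errors")
    tab = _wald_table(res)
    return RegressionResult(
        model="poisson",
        metric=metric,
        n=len(dataset),
        params=tab,
        ratio_per_unit_log=_per_unit_ratio(tab, f"log_{metric}"),
    )


def ratio_per_10pct(result: RegressionResult) -> RegressionResult:
    """Derive the odds/rate ratio for a 10% increase in the raw traffic metric.

    Valid only when the metric entered the model in natural log, in which
    case a 10% increase shifts the covariate by ln 1.1 and the ratio is
    exp(beta * ln 1.1); CI bounds transform identically.
    """
    if not result.log_metric:
        raise ContractError("per-10% ratio requires a log-transformed metric")
    row = result.params.loc[result.metric_term]
    scale = math.log(1.1)
    result.ratio_per_10pct_ci = (
        float(np.exp(row["estimate"] * scale)),
        float(np.exp(row["ci_lo"] * scale)),
        float(np.exp(row["ci_hi"] * scale)),
    )
    return result


# ---------------------------------------------------------------------------
# Cohort margins and reporting
# ---------------------------------------------------------------------------

AGE_BAND_EDGES = ((0, 5), (5, 10), (10, 20), (20, 65), (65, None))
AGE_BAND_LABELS = ("0-4", "5-9", "10-19", "20-64", ">=65")
POVERTY_BAND_LABELS = ("0", "1-10", "11-20", "20-30", ">30")


def _poverty_band(p: float) -> str:
    if p < 1.0:
        return "0"
    if p <= 10.0:
        return "1-10"
    if p <= 20.0:
        return "11-20"
    if p <= 30.0:
        return "20-30"
    return ">30"


def _age_band(a: float) -> str:
    for (lo, hi), lab in zip(AGE_BAND_EDGES, AGE_BAND_LABELS):
        if hi is None or a < hi:
            return lab
    return AGE_BAND_LABELS[-1]


def population_margins(persons: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of the cohort by sex, age band and poverty band.

    Returns a tidy table (characteristic, category, count, percent) whose
    group counts each sum to the cohort total; percent = 100 * count / total.
    """
    n = len(persons)
    if n == 0:
        raise ValueError("empty cohort")
    rows = [("total", "all", n, 100.0)]
    sex_counts = persons["sex"].value_counts()
    for cat in ("male", "female"):
        c = int(sex_counts.get(cat, 0))
        rows.append(("sex", cat, c, 100.0 * c / n))
    bands = persons["age"].map(_age_band)
    for lab in AGE_BAND_LABELS:
        c = int((bands == lab).sum())
        rows.append(("age", lab, c, 100.0 * c / n))
    pbands = persons["poverty_index"].map(_poverty_band)
    for lab in POVERTY_BAND_LABELS:
        c = int((pbands == lab).sum())
        rows.append(("poverty", lab, c, 100.0 * c / n))
    return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])


def _result_block(r: RegressionResult) -> dict:
    block = {
        "model": r.model,
        "metric": r.metric,
        "n": r.n,
        "coefficients": {
            name: {
                "estimate": round(float(row["estimate"]), 10),
                "se": round(float(row["se"]), 10),
                "ci_lo": round(float(row["ci_lo"]), 10),
                "ci_hi": round(float(row["ci_hi"]), 10),
            }
            for name, row in r.params.iterrows()
        },
    }
    if r.ratio_per_unit_log is not None:
        e, lo, hi = r.ratio_per_unit_log
        block["ratio_per_unit_log"] = {
            "estimate": round(e, 10), "ci_lo": round(lo, 10), "ci_hi": round(hi, 10)
        }
    if r.ratio_per_10pct_ci is not None:
        e, lo, hi = r.ratio_per_10pct_ci
        block["ratio_per_10pct"] = {
            "estimate": round(e, 10), "ci_lo": round(lo, 10), "ci_hi": round(hi, 10)
        }
    return block


def report(
    summaries: list[QuintileSummary],
    results: list[RegressionResult],
    out_dir,
) -> dict:
    """Write the machine-readable results file and the quintile figure.

    Produces ``results.json`` (one block per model x metric), ``quintiles.csv``
    and ``fig_quintiles.png`` (mean exacerbations/person-year by quintile for
    each metric).  Rerunning on identical inputs is byte-identical for the
    JSON and CSV outputs.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "results": [_result_block(r) for r in results],
        "quintiles": {
            s.metric: s.table.round(10).to_dict(orient="records") for s in summaries
        },
    }
    with open(out_dir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    qt = pd.concat(
        [s.table.assign(metric=s.metric) for s in summaries], ignore_index=True
    )[["metric", "quintile", "lo", "hi", "n", "mean_rate"]]
    qt.to_csv(out_dir / "quintiles.csv", index=False, float_format="%.10g")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(summaries), figsize=(4 * len(summaries), 3.2),
                             squeeze=False)
    for ax, s in zip(axes[0], summaries):
        ax.bar(s.table["quintile"], s.table["mean_rate"], color="#4878a8")
        ax.set_xlabel(f"{s.metric} quintile")
        ax.set_ylabel("mean exacerbations / person-year")
        ax.set_title(s.metric)
    fig.tight_layout()
    fig.savefig(out_dir / "fig_quintiles.png", dpi=120)
    plt.close(fig)
    return payload
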