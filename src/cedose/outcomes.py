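"""Survival, response and correlation analyses for the treated cohort.

Covers the trial-style statistical battery: Kaplan–Meier estimation with
Brookmeyer–Crowley median confidence intervals and landmark survival,
log-rank comparison of dose groups (absorbed dose dichotomized at 100 Gy),
covariate-adjusted lognormal accelerated failure time (AFT) regression with
fold changes per stated covariate increments, Pearson correlation screens,
and best-response / demographics tabulation.

Conventions: two-sided alpha = 0.05, no multiplicity correction; the KM
median is the smallest time with S(t) <= 0.5; fold change = exp(beta x
increment) with Wald 95% CIs on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, LogNormalAFTFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class PatientRecord:
    """Row unit of the cohort table (dosing, covariates, outcomes)."""

    id: str
    cohort: int
    administered_mCi: float
    infused_mL: float
    n_catheters: int
    age_y: float
    ecog: int
    baseline_tumor_mL: float
    absorbed_dose_Gy: float
    tvt_percent: float
    os_months: float
    os_event: bool
    pfs_months: float
    pfs_event: bool
    best_response: str

    def __post_init__(self) -> None:
        if self.ecog not in (0, 1, 2):
            raise ValueError(f"ECOG must be 0/1/2, got {self.ecog}")
        if not 1 <= self.n_catheters <= 4:
            raise ValueError(f"catheters must be 1..4, got {self.n_catheters}")
        if self.os_months < 0 or self.pfs_months < 0:
            raise ValueError("survival times must be nonnegative")
        if self.best_response not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown best-response label {self.best_response!r}")


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class KMEstimate:
    """Product-limit survival estimate with median CI and landmarks."""

    survival: pd.DataFrame  # index: time, column 'S'
    median_months: float | None
    median_ci95: tuple[float, float]
    n: int
    events: int
    landmarks: dict[float, tuple[float, float]] = field(default_factory=dict)
    #: (S(t), Greenwood SE) at each requested landmark time


@dataclass
class AFTFit:
    """Lognormal AFT fit: coefficients on log-time, scale, fold changes."""

    coefficients: pd.Series
    coefficient_ci95: pd.DataFrame
    sigma: float
    log_likelihood: float
    fold_changes: pd.DataFrame  # index: covariate; columns increment/fold_change/lo/hi
    n: int
    events: int
    fitter: LogNormalAFTFitter | None = None


def _greenwood_se(times: np.ndarray, events: np.ndarray, at: float) -> float:
    """Greenwood standard error of S(at) from the raw data."""
    order = np.argsort(times)
    t, e = times[order], events[order]
    n_at_risk = len(t)
    s = 1.0
    var_sum = 0.0
    for ti in np.unique(t[e.astype(bool)]):
        if ti > at:
            break
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & e.astype(bool)).sum())
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            var_sum += d_i / (n_i * (n_i - d_i))
    return s * math.sqrt(var_sum)


def km_fit(
    times: Sequence[float],
    events: Sequence[bool],
    landmark_times: Sequence[float] = (9.0,),
    label: str = "KM_estimate",
) -> KMEstimate:
    """Kaplan–Meier estimate with Brookmeyer–Crowley median CI.

    The median CI comes from inverting the pointwise log-log (exp(-exp))
    confidence band of S(t) — the Brookmeyer–Crowley construction.  An
    undefined median (S never reaches 0.5) is reported as None.  Landmark
    survival (e.g. S at 9 months) is returned with its Greenwood SE.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("survival times must be nonnegative")
    if not events.any() and np.all(times == 0):
        raise ValueError("all subjects censored at time 0: nothing to estimate")
    kmf = KaplanMeierFitter(label=label).fit(times, events)
    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    landmarks = {
        float(t): (float(kmf.predict(t)), _greenwood_se(times, events, t))
        for t in landmark_times
    }
    surv = kmf.survival_function_.rename(columns={label: "S"})
    return KMEstimate(
        survival=surv,
        median_months=median,
        median_ci95=(lo, hi),
        n=len(times),
        events=int(events.sum()),
        landmarks=landmarks,
    )


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Standard 1-df log-rank test; returns (chi-square statistic, p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    for t, e in ((ta, ea), (tb, eb)):
        if not e.any() and np.all(t == 0):
            raise ValueError("a group with no events and no follow-up is degenerate")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def aft_lognormal_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    endpoint: Literal["OS", "PFS"] = "OS",
    duration_col: str | None = None,
    event_col: str | None = None,
    increments: dict[str, float] | None = None,
) -> AFTFit:
    """Right-censored lognormal AFT regression with fold changes.

    Models log(T) = intercept + X beta + sigma epsilon by maximum likelihood.
    ``increments`` maps covariate -> reporting increment; the fold change is
    exp(beta x increment) — e.g. increment 10 for "per 10 percentage points of
    tumor coverage", 100 for "per 100 Gy" — with Wald 95% CIs exponentiated
    from the log scale.  Defaults to the unit increment.
    """
    duration_col = duration_col or f"{endpoint.lower()}_months"
    event_col = event_col or f"{endpoint.lower()}_event"
    cols = [duration_col, event_col, *covariates]
    df = data[cols].dropna().copy()
    n = len(df)
    events = int(df[event_col].sum())
    if n <= len(covariates) + 2:
        raise ValueError(f"n={n} too small for {len(covariates)} covariates")
    if events < 2:
        raise ValueError("need at least 2 events to fit an AFT model")
    df[event_col] = df[event_col].astype(bool)
    # lognormal support excludes 0; nudge exact zeros to half the smallest
    # positive duration rather than dropping subjects
    pos = df[duration_col] > 0
    if not pos.all():
        df.loc[~pos, duration_col] = df.loc[pos, duration_col].min() / 2.0
    fitter = LogNormalAFTFitter()
    try:
        fitter.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(
            f"lognormal AFT fit failed for endpoint {endpoint}: {exc}"
        ) from exc
    beta = fitter.params_.loc["mu_"].drop("Intercept")
    ci = fitter.confidence_intervals_.loc["mu_"].drop("Intercept")
    ci.columns = ["lo", "hi"]
    sigma = float(np.exp(fitter.params_.loc[("sigma_", "Intercept")]))
    increments = increments or {}
    rows = []
    for cov in covariates:
        inc = increments.get(cov, 1.0)
        rows.append(
            {
                "covariate": cov,
                "increment": inc,
                "fold_change": math.exp(beta[cov] * inc),
                "lo": math.exp(ci.loc[cov, "lo"] * inc),
                "hi": math.exp(ci.loc[cov, "hi"] * inc),
            }
        )
    fold = pd.DataFrame(rows).set_index("covariate")
    return AFTFit(
        coefficients=beta,
        coefficient_ci95=ci,
        sigma=sigma,
        log_likelihood=float(fitter.log_likelihood_),
        fold_changes=fold,
        n=n,
        events=events,
        fitter=fitter,
    )


def correlation_screen(
    data: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """Correlation (r, p) for each requested column pair.

    Missing data are dropped pairwise; a pair with fewer than 3 complete
    observations or zero variance is returned with NaN r/p and an explanatory
    note rather than silently computed.
    """
    rows = []
    for x, y in pairs:
        sub = data[[x, y]].dropna()
        n = len(sub)
        note = ""
        r = p = float("nan")
        if n < 3:
            note = f"only {n} complete pairs"
        elif sub[x].nunique() < 2 or sub[y].nunique() < 2:
            note = "zero variance"
        else:
            if method == "pearson":
                r, p = stats.pearsonr(sub[x], sub[y])
            else:
                r, p = stats.spearmanr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "n": n, "r": r, "p": p, "note": note})
    return pd.DataFrame(rows)


def response_table(data: pd.DataFrame, cohort_col: str = "cohort") -> dict:
    """Best-response counts by cohort, overall percents, and ORR.

    ORR = (CR + PR) / n.  Percentages to one decimal.  Unknown response
    labels are rejected rather than lumped.
    """
    labels = data["best_response"]
    bad = set(labels) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown best-response categories: {sorted(bad)}")
    counts = (
        data.groupby(cohort_col)["best_response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=RESPONSE_CATEGORIES, fill_value=0)
    )
    n = len(data)
    overall = counts.sum(axis=0)
    percents = (100.0 * overall / n).round(1)
    orr = float(overall["CR"] + overall["PR"]) / n
    return {
        "by_cohort": counts,
        "overall_counts": overall,
        "overall_percent": percents,
        "n": n,
        "orr_percent": round(100.0 * orr, 1),
    }


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Pooled mean from per-group means weighted by group size."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float((means * ns).sum() / ns.sum())


def cohort_summary(
    data: pd.DataFrame,
    continuous: Sequence[str] = ("age_y", "baseline_tumor_mL"),
    categorical: Sequence[str] = ("ecog",),
    cohort_col: str = "cohort",
) -> dict:
    """Demographics table: per-cohort and pooled mean +/- SD (range) for
    continuous variables; counts and percents for categorical ones."""
    out: dict = {"n_by_cohort": data[cohort_col].value_counts().sort_index(), "n": len(data)}
    cont = {}
    for col in continuous:
        g = data.groupby(cohort_col)[col]
        tab = pd.DataFrame(
            {"mean": g.mean(), "sd": g.std(ddof=1), "min": g.min(), "max": g.max(), "n": g.size()}
        )
        pooled = {
            "mean": pooled_mean(tab["mean"], tab["n"]),
            "sd": float(data[col].std(ddof=1)),
            "min": float(data[col].min()),
            "max": float(data[col].max()),
            "n": len(data),
        }
        cont[col] = {"by_cohort": tab, "pooled": pooled}
    out["continuous"] = cont
    cat = {}
    for col in categorical:
        counts = data.groupby(cohort_col)[col].value_counts().unstack(fill_value=0)
        overall = counts.sum(axis=0)
        cat[col] = {
            "by_cohort": counts,
            "overall_counts": overall,
            "overall_percent": (100.0 * overall / len(data)).round(1),
        }
    out["categorical"] = cat
    return out
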