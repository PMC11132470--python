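"""Statistical pipeline for the music/speech judgment experiments.

Stages, in the order they run on a dataset:

1. exclusions (completion, headphone screening, constant responding, probe
   accuracy < 90%, and — for the detection experiments — response bias
   outside 50 +/- 15% in any task);
2. per-participant psychometric fits: trial-level OLS of the binary
   response on the manipulated AM parameter, and a bounded logistic
   ``f(x; a, s) = 1 / (1 + exp(-s (x - a)))`` fitted by least squares so
   its R^2 is on the same footing as the linear fit;
3. group inference: one-sample t on slopes with Cohen's d; Pearson
   correlations of slope with musical sophistication (reported with and
   without flagged outliers; subscale screening at the Bonferroni-corrected
   threshold); an unequal-variance (Welch) t-test between participants
   split by slope sign;
4. a noncentral-t power analysis for planning sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "StatsReport",
    "apply_exclusions",
    "fit_linear",
    "fit_logistic",
    "fit_participants",
    "compare_models",
    "one_sample_slope_test",
    "correlate",
    "split_group_welch",
    "power_required_n",
    "power_one_sample_t",
    "cohens_d_from_summary",
    "reconcile_exclusion_counts",
    "PROBE_ACCURACY_MIN",
    "BIAS_WINDOW",
    "SUBSCALE_ALPHA",
]

#: Minimum probe-trial accuracy to be retained.
PROBE_ACCURACY_MIN = 0.90
#: Acceptable response-1 rate window in the detection tasks (50 +/- 15%).
BIAS_WINDOW = (0.35, 0.65)
#: Bonferroni-corrected threshold for the five subscale correlations.
SUBSCALE_ALPHA = 0.01


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

EXCLUSION_CRITERIA = ("incomplete", "headphone", "all_same", "probe_accuracy", "response_bias")


def apply_exclusions(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    check_bias: bool | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Filter participants; return (included ids, per-criterion ledger).

    Criteria apply in order and each participant is counted under the first
    one that catches them: incomplete session or questionnaire, failed
    headphone screening, identical response on every testing trial, probe
    accuracy below 90%, and (detection experiments only, or whenever
    ``check_bias`` is forced on) a response-1 rate outside 35–65% in any
    task.
    """
    required = {"participant_id", "kind", "task", "response", "probe_correct"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses table is missing columns: {sorted(missing)}")
    if check_bias is None:
        tasks = set(responses.loc[responses["kind"] == "testing", "task"].unique())
        check_bias = tasks != {"judgment"}

    pinfo = participants.set_index("participant_id")
    ledger = {c: 0 for c in EXCLUSION_CRITERIA}
    included = []
    for pid, sub in responses.groupby("participant_id", sort=True):
        testing = sub[sub["kind"] == "testing"]
        probes = sub[sub["kind"] == "probe"]
        row = pinfo.loc[pid] if pid in pinfo.index else None
        if row is not None and not (bool(row.get("completed", True))):
            ledger["incomplete"] += 1
            continue
        if row is not None and not bool(row.get("headphone_pass", True)):
            ledger["headphone"] += 1
            continue
        if testing["response"].nunique() <= 1:
            ledger["all_same"] += 1
            continue
        if len(probes) and probes["probe_correct"].mean() < PROBE_ACCURACY_MIN:
            ledger["probe_accuracy"] += 1
            continue
        if check_bias:
            rates = testing.groupby("task")["response"].mean()
            if ((rates < BIAS_WINDOW[0]) | (rates > BIAS_WINDOW[1])).any():
                ledger["response_bias"] += 1
                continue
        included.append(pid)
    return included, ledger


def reconcile_exclusion_counts(recruited: int, per_criterion_counts: list[int]) -> int:
    """Included sample size implied by recruitment and exclusion counts."""
    if any(c < 0 for c in per_criterion_counts):
        raise ValueError("exclusion counts must be nonnegative")
    n = recruited - sum(per_criterion_counts)
    if n < 0:
        raise ValueError("exclusions exceed recruitment")
    return n


# ---------------------------------------------------------------------------
# Per-participant psychometric fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricFit:
    """Linear and logistic fits of one participant (per grouping key)."""

    participant_id: str
    slope: float
    intercept: float
    r2_lin: float
    log_a: float = math.nan
    log_slope: float = math.nan
    r2_log: float = math.nan
    group: str | float | None = None
    converged: bool = True


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0  # zero-variance convention; such data are excluded upstream
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Trial-level OLS of binary responses on the stimulus parameter.

    Returns (slope, intercept, R^2).  Constant responses give slope 0 by
    convention (they are normally removed by the exclusion filters).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct stimulus levels")
    if np.unique(y).size < 2:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    return float(res.slope), float(res.intercept), _r2(y, yhat)


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    level_bounds: tuple[float, float],
    n_starts: int = 5,
) -> tuple[float, float, float, bool]:
    """Least-squares logistic fit with the midpoint bounded to the levels.

    Fits ``1 / (1 + exp(-s (x - a)))`` with ``a`` constrained to
    ``level_bounds`` (the extreme stimulus levels).  Least squares rather
    than maximum likelihood keeps R^2 directly comparable with the linear
    fit.  Multi-start over a grid of midpoints and slopes; returns
    (a, s, R^2, converged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct stimulus levels")
    lo, hi = level_bounds

    def model(theta: np.ndarray) -> np.ndarray:
        a, s = theta
        return 1.0 / (1.0 + np.exp(-np.clip(s * (x - a), -500, 500)))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - y

    span = hi - lo
    starts = [
        (lo + f * span, s0)
        for f, s0 in zip(
            np.linspace(0.2, 0.8, n_starts),
            [2.0 / span, -2.0 / span, 8.0 / span, 0.5 / span, -8.0 / span],
        )
    ]
    best = None
    for a0, s0 in starts:
        fit = optimize.least_squares(
            residuals, x0=[a0, s0], bounds=([lo, -np.inf], [hi, np.inf])
        )
        if best is None or fit.cost < best.cost:
            best = fit
    a, s = best.x
    return float(a), float(s), _r2(y, model(best.x)), bool(best.success)


def fit_participants(
    responses: pd.DataFrame,
    included: list[str] | None = None,
    group_by: str | None = None,
    x_col: str = "x_value",
    with_logistic: bool = True,
) -> list[PsychometricFit]:
    """Per-participant fits on testing trials, optionally per grouping key.

    ``group_by`` supports designs where slopes are estimated separately
    within a second factor (e.g. regressing on sigma under each peak
    frequency): one fit per (participant, group) pair.
    """
    data = responses[responses["kind"] == "testing"]
    if included is not None:
        data = data[data["participant_id"].isin(included)]
    fits = []
    keys = ["participant_id"] + ([group_by] if group_by else [])
    for key, sub in data.groupby(keys, sort=True):
        pid = key[0] if isinstance(key, tuple) else key
        group = key[1] if (isinstance(key, tuple) and len(key) > 1) else None
        x = sub[x_col].to_numpy(dtype=float)
        y = sub["response"].to_numpy(dtype=float)
        slope, intercept, r2_lin = fit_linear(x, y)
        if with_logistic:
            bounds = (float(x.min()), float(x.max()))
            a, s, r2_log, ok = fit_logistic(x, y, bounds)
        else:
            a = s = r2_log = math.nan
            ok = True
        fits.append(
            PsychometricFit(
                participant_id=str(pid),
                slope=slope,
                intercept=intercept,
                r2_lin=r2_lin,
                log_a=a,
                log_slope=s,
                r2_log=r2_log,
                group=group,
                converged=ok,
            )
        )
    return fits


def compare_models(fits: list[PsychometricFit]) -> float:
    """Paired mean R^2 difference, linear minus logistic."""
    diffs = [f.r2_lin - f.r2_log for f in fits if not math.isnan(f.r2_log)]
    if not diffs:
        raise ValueError("no logistic fits to compare")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Group-level inference
# ---------------------------------------------------------------------------


def one_sample_slope_test(slopes: np.ndarray, popmean: float = 0.0) -> dict:
    """One-sample t-test of slopes against ``popmean``, with Cohen's d."""
    slopes = np.asarray(slopes, dtype=float)
    n = slopes.size
    if n < 2:
        raise ValueError("need at least 2 slopes")
    sd = slopes.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in slopes")
    res = stats.ttest_1samp(slopes, popmean)
    return {
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "d": float((slopes.mean() - popmean) / sd),
        "mean": float(slopes.mean()),
        "n": n,
    }


def _flag_outliers(x: np.ndarray, y: np.ndarray, z_threshold: float) -> np.ndarray:
    """Indices with |standardized residual| above threshold, from the OLS line."""
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sd = resid.std(ddof=2) if len(x) > 2 else resid.std(ddof=0)
    if sd == 0:
        return np.array([], dtype=int)
    return np.where(np.abs(resid / sd) > z_threshold)[0]


def correlate(
    slopes: np.ndarray,
    covariate: np.ndarray,
    outlier_z: float = 3.0,
) -> dict:
    """Pearson correlation of slopes with a covariate, with and without
    flagged outliers.

    Outliers are points whose standardized residual from the bivariate OLS
    line exceeds ``outlier_z`` in magnitude; both estimates are always
    reported.  df = n - 2.
    """
    x = np.asarray(slopes, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    out = {"r": float(r), "df": x.size - 2, "p": float(p), "n_outliers": 0}
    outliers = _flag_outliers(x, y, outlier_z)
    if outliers.size and x.size - outliers.size >= 3:
        keep = np.setdiff1d(np.arange(x.size), outliers)
        r2_, p2_ = stats.pearsonr(x[keep], y[keep])
        out.update(
            n_outliers=int(outliers.size),
            r_no_outlier=float(r2_),
            df_no_outlier=int(keep.size - 2),
            p_no_outlier=float(p2_),
        )
    return out


def split_group_welch(slopes: np.ndarray, covariate: np.ndarray, split_at: float = 0.0) -> dict:
    """Welch two-sample t-test on the covariate between slope-sign groups.

    Splits participants at ``slope = split_at``; degrees of freedom are the
    fractional Welch–Satterthwaite value; Cohen's d uses the pooled SD.
    """
    slopes = np.asarray(slopes, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    hi = covariate[slopes > split_at]
    lo = covariate[slopes <= split_at]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both slope groups need at least 2 members")
    res = stats.ttest_ind(hi, lo, equal_var=False)
    v1, v2 = hi.var(ddof=1), lo.var(ddof=1)
    n1, n2 = len(hi), len(lo)
    df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    sd_pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "d": float(abs(hi.mean() - lo.mean()) / sd_pooled),
        "n_positive": n1,
        "n_nonpositive": n2,
    }


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------


def power_one_sample_t(n: int, d: float, alpha: float) -> float:
    """Power of a two-tailed one-sample t-test at effect size d, size n."""
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * math.sqrt(n)
    return float(1.0 - stats.nct.cdf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


def power_required_n(d: float, alpha: float, power: float, n_max: int = 100_000) -> int:
    """Smallest n whose two-tailed one-sample t-test reaches target power.

    Exact noncentral-t computation with noncentrality ``d * sqrt(n)`` and
    ``df = n - 1``, searched over integers.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_one_sample_t(n, d, alpha) >= power:
            return n
    raise ValueError(f"power {power} not attainable within n <= {n_max}")


def cohens_d_from_summary(mean1: float, mean2: float, sd: float) -> float:
    """|mean1 - mean2| / sd, for comparisons against a published norm."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return abs(mean1 - mean2) / sd


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class StatsReport:
    """Per-participant fits plus group-level inference and exclusion ledger."""

    experiment_id: int
    n_recruited: int
    n_included: int
    exclusion_ledger: dict[str, int]
    fits: list[PsychometricFit] = field(repr=False)
    slope_tests: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    split_tests: dict = field(default_factory=dict)
    mean_r2: float = math.nan
    se_r2: float = math.nan
    mean_r2_difference: float = math.nan

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "n_recruited": self.n_recruited,
            "n_included": self.n_included,
            "exclusion_ledger": dict(self.exclusion_ledger),
            "mean_r2": self.mean_r2,
            "se_r2": self.se_r2,
            "mean_r2_difference": self.mean_r2_difference,
            "slope_tests": self.slope_tests,
            "correlations": self.correlations,
            "split_tests": self.split_tests,
            "fits": [
                {
                    "participant_id": f.participant_id,
                    "group": f.group,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r2_lin": f.r2_lin,
                    "log_a": f.log_a,
                    "log_slope": f.log_slope,
                    "r2_log": f.r2_log,
                }
                for f in self.fits
            ],
        }


def analyze_experiment(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    experiment_id: int,
    group_by: str | None = None,
    with_logistic: bool = True,
) -> StatsReport:
    """Run the full pipeline on one experiment's response tables.

    For the grouped designs (slopes per second factor) pass ``group_by``;
    slope tests, correlations and split tests are then computed within each
    group and within each task.
    """
    included, ledger = apply_exclusions(responses, participants)
    n_recruited = responses["participant_id"].nunique()

    msi = participants.set_index("participant_id")["msi_general"]
    tasks = sorted(responses.loc[responses["kind"] == "testing", "task"].unique())
    fits_all: list[PsychometricFit] = []
    slope_tests: dict = {}
    correlations: dict = {}
    split_tests: dict = {}
    for task in tasks:
        task_resp = responses[(responses["task"] == task) | (responses["kind"] == "probe")]
        fits = fit_participants(task_resp, included, group_by=group_by, with_logistic=with_logistic)
        fits_all.extend(fits)
        groups = sorted({f.group for f in fits}, key=str)
        for group in groups:
            gf = [f for f in fits if f.group == group]
            slopes = np.array([f.slope for f in gf])
            cov = msi.reindex([f.participant_id for f in gf]).to_numpy()
            key = task if group is None else f"{task}|{group}"
            slope_tests[key] = one_sample_slope_test(slopes)
            if np.isfinite(cov).all() and cov.std() > 0:
                # covariate analyses need enough participants per group;
                # small pilots simply omit them
                try:
                    correlations[key] = correlate(slopes, cov)
                except ValueError:
                    pass
                try:
                    split_tests[key] = split_group_welch(slopes, cov)
                except ValueError:
                    pass

    r2 = np.array([f.r2_lin for f in fits_all])
    report = StatsReport(
        experiment_id=experiment_id,
        n_recruited=n_recruited,
        n_included=len(included),
        exclusion_ledger=ledger,
        fits=fits_all,
        slope_tests=slope_tests,
        correlations=correlations,
        split_tests=split_tests,
        mean_r2=float(r2.mean()) if len(r2) else math.nan,
        se_r2=float(r2.std(ddof=1) / math.sqrt(len(r2))) if len(r2) > 1 else math.nan,
    )
    if with_logistic:
        report.mean_r2_difference = compare_models(fits_all)
    return report
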