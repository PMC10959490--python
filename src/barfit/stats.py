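"""Trade-off statistics: detection limits, lineage classification,
treatment-level mixed models, cross-environment genetic-correlation slopes,
and the no-cost-line cost-of-generalization statistic.

Fitness changes (dw) are in percentage points throughout, so the study's
detection limits (2.163 for single lineages, 0.634 vs zero, 0.306 between
treatments) apply on one scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("barfit")


@dataclass(frozen=True)
class PowerSpec:
    """Detection-limit configuration.

    ``rmse`` is the empirical s.d. of fitness change (percentage points) and
    ``psd`` the population s.d. (stored verbatim; units ambiguous in the
    source data, unused in derivations).  The three limits are the smallest
    effects detectable at 80% power: per-lineage, treatment-vs-zero, and
    between-treatment.
    """

    rmse: float = 2.419
    psd: float = 0.009
    alpha: float = 0.05
    power: float = 0.80
    limit_lineage: float = 2.163
    limit_treatment_zero: float = 0.634
    limit_between_treatments: float = 0.306

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        for name in ("limit_lineage", "limit_treatment_zero", "limit_between_treatments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ------------------------------------------------------------------ power


def t_test_power(
    effect: float,
    sd: float,
    n: int,
    alpha: float = 0.05,
    test: Literal["one_sample", "two_sample"] = "one_sample",
) -> float:
    """Power of a two-sided t-test for a true mean difference ``effect``.

    Exact noncentral-t computation; ``two_sample`` assumes equal group sizes n.
    """
    if test == "one_sample":
        df = n - 1
        nc = effect / (sd / np.sqrt(n))
    elif test == "two_sample":
        df = 2 * n - 2
        nc = effect / (sd * np.sqrt(2.0 / n))
    else:
        raise ValueError(f"unknown test {test!r}")
    if df < 1:
        raise ValueError("need n >= 2")
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = 1.0 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(power):
        # noncentral t is numerically fragile at very large df; use its
        # normal limit there
        power = sps.norm.cdf(nc - tcrit) + sps.norm.cdf(-nc - tcrit)
    return float(power)


def min_detectable_effect(
    sd: float,
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    test: Literal["one_sample", "two_sample"] = "one_sample",
) -> float:
    """Smallest true effect a two-sided t-test detects at the requested power.

    Found by root-finding on the noncentral-t power function.  Same units as
    ``sd`` (percentage points for fitness changes).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n < 2:
        raise ValueError("need n >= 2")

    def gap(effect: float) -> float:
        return t_test_power(effect, sd, n, alpha, test) - power

    hi = sd
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * sd:
            raise RuntimeError(f"power root-finding failed to bracket in (0, {hi}]")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10))


# ------------------------------------------------------------------ classification


def classify_lineages(dw, limit: float = 2.163) -> pd.Series:
    """Per-lineage fitness-change call at the detection limit.

    increased iff dw >= limit; decreased iff dw <= -limit; else unchanged;
    missing dw -> ``unclassified``.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    dw = pd.Series(np.asarray(dw, dtype=float))
    out = pd.Series("unchanged", index=dw.index, dtype=object)
    out[dw >= limit] = "increased"
    out[dw <= -limit] = "decreased"
    out[dw.isna()] = "unclassified"
    return out


# ------------------------------------------------------------------ mixed model


def fit_treatment_effects(
    dw: pd.DataFrame,
    include_intercept: bool = False,
) -> pd.DataFrame:
    """Treatment effects on fitness change via a linear mixed-effects model.

    Fits ``dw ~ treatment`` (without intercept by default, so each estimate is
    a treatment mean tested against zero; with intercept, non-reference terms
    are contrasts against the first treatment) with a random intercept per
    ``line_id``.  Expects one table per (chemical, assay environment) with
    replicate-level rows.  Singular fits fall back to ordinary least squares
    on line means (logged).

    Returns a frame with term, estimate, se, tvalue, pvalue.
    """
    required = {"dw", "treatment", "line_id"}
    if not required <= set(dw.columns):
        raise ValueError(f"dw table needs columns {sorted(required)}")
    data = dw.dropna(subset=["dw"]).copy()
    if data.empty:
        raise ValueError("no non-missing fitness changes to fit")
    formula = "dw ~ treatment + 0" if not include_intercept else "dw ~ treatment"

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["line_id"])
            fit = model.fit(reml=True)
        singular = not np.isfinite(fit.cov_re.iloc[0, 0]) or np.any(
            ~np.isfinite(fit.bse_fe)
        )
    except Exception as exc:  # pragma: no cover - rare numerical failures
        logger.warning("mixed model failed (%s); falling back to line-mean OLS", exc)
        singular = True
        fit = None

    if singular or fit is None:
        logger.warning("singular mixed fit; falling back to OLS on line means")
        means = data.groupby(["line_id", "treatment"], as_index=False)["dw"].mean()
        ols = smf.ols(formula, means).fit()
        est, se, tv, pv = ols.params, ols.bse, ols.tvalues, ols.pvalues
    else:
        est, se = fit.fe_params, fit.bse_fe
        tv = est / se
        # t-approximation with residual-based degrees of freedom
        dof = max(int(len(data) - len(est) - data["line_id"].nunique()), 1)
        pv = pd.Series(2.0 * sps.t.sf(np.abs(tv), dof), index=est.index)

    out = pd.DataFrame(
        {"term": est.index, "estimate": est.values, "se": se.values,
         "tvalue": np.asarray(tv), "pvalue": np.asarray(pv)}
    )
    out["term"] = out["term"].str.replace(r"treatment\[(T\.)?(.+)\]", r"\2", regex=True)
    return out.reset_index(drop=True)


# ------------------------------------------------------------------ slopes


@dataclass(frozen=True)
class CorrelationResult:
    """Cross-environment genetic correlation as the slope of the line joining
    the two constant-treatment mean fitness changes in the (low-stress,
    high-stress) plane."""

    env_pair: tuple[float, float]
    point_a: tuple[float, float]
    point_b: tuple[float, float]
    slope: float

    @property
    def direction(self) -> str:
        if self.slope > 0:
            return "positive"
        if self.slope < 0:
            return "negative"
        return "zero"


def genetic_correlation_slope(
    point_a: Sequence[float],
    point_b: Sequence[float],
    env_pair: tuple[float, float] = (0.0, 0.8),
) -> CorrelationResult:
    """Slope between two treatment mean points; undefined for equal x."""
    ax, ay = float(point_a[0]), float(point_a[1])
    bx, by = float(point_b[0]), float(point_b[1])
    if ax == bx:
        raise ValueError("slope undefined: the two points share an x-coordinate")
    slope = (by - ay) / (bx - ax)
    return CorrelationResult(env_pair=env_pair, point_a=(ax, ay), point_b=(bx, by), slope=slope)


def bootstrap_slope(
    dw: pd.DataFrame,
    treatment_a: str,
    treatment_b: str,
    env_low: float,
    env_high: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Nonparametric bootstrap (over lineages) percentile CI for a slope.

    ``dw`` needs columns lineage, treatment, stress_fraction, dw.
    """
    wide = (
        dw[dw["stress_fraction"].isin([env_low, env_high])]
        .pivot_table(index=["lineage", "treatment"], columns="stress_fraction", values="dw")
        .reset_index()
    )
    rng = np.random.default_rng(seed)
    slopes = []
    a = wide[wide["treatment"] == treatment_a]
    b = wide[wide["treatment"] == treatment_b]
    if a.empty or b.empty:
        raise ValueError("both treatments must be present")
    point = lambda grp: (grp[env_low].mean(), grp[env_high].mean())
    obs = genetic_correlation_slope(point(a), point(b), (env_low, env_high)).slope
    for _ in range(n_boot):
        ra = a.sample(len(a), replace=True, random_state=rng.integers(2**31))
        rb = b.sample(len(b), replace=True, random_state=rng.integers(2**31))
        try:
            slopes.append(
                genetic_correlation_slope(point(ra), point(rb), (env_low, env_high)).slope
            )
        except ValueError:
            continue
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return obs, (float(lo), float(hi))


# ------------------------------------------------------------------ no-cost line


@dataclass(frozen=True)
class NoCostLine:
    """Line through the EH0 and EH80 mean points in the (0%, 80%) dw plane.

    ``normal`` is unit length and oriented toward the jointly-higher-fitness
    (benefit) side: its dot product with (1, 1) is positive, or with ties,
    its x-component is positive.
    """

    point: tuple[float, float]
    direction: tuple[float, float]
    normal: tuple[float, float]


def no_cost_line(p_eh0: Sequence[float], p_eh80: Sequence[float]) -> NoCostLine:
    p1 = np.asarray(p_eh0, dtype=float)
    p2 = np.asarray(p_eh80, dtype=float)
    d = p2 - p1
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("no-cost line undefined: coincident points")
    d = d / norm
    n = np.array([-d[1], d[0]])
    s = n @ np.array([1.0, 1.0])
    if s < 0 or (s == 0 and n[0] < 0):
        n = -n
    return NoCostLine(point=tuple(p1), direction=tuple(d), normal=tuple(n))


def orthogonal_cost(points, line: NoCostLine) -> np.ndarray:
    """Signed orthogonal distance of dw points to the no-cost line.

    Negative = below/left of the line (a cost of generalization), positive =
    above/right (a net benefit).  Units: percentage points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = (pts - np.asarray(line.point)) @ np.asarray(line.normal)
    return d if d.size > 1 else d


def classify_cost(distance, limit: float) -> pd.Series:
    """cost iff distance <= -limit; benefit iff >= +limit; else no_cost."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    d = pd.Series(np.atleast_1d(np.asarray(distance, dtype=float)))
    out = pd.Series("no_cost", index=d.index, dtype=object)
    out[d <= -limit] = "cost"
    out[d >= limit] = "benefit"
    out[d.isna()] = "unclassified"
    return out


def summarize_costs(costs: pd.DataFrame) -> pd.DataFrame:
    """Counts, fractions and mean signed distance per treatment and pooled.

    ``costs`` needs columns treatment, distance, category.  The pooled row is
    labelled ``"all"``.
    """
    if costs.empty:
        return pd.DataFrame(
            columns=["treatment", "n", "cost", "no_cost", "benefit",
                     "frac_cost", "frac_no_cost", "frac_benefit", "mean_distance"]
        )

    def one(group: pd.DataFrame, label: str) -> dict:
        cls = group[group["category"] != "unclassified"]
        n = len(cls)
        counts = cls["category"].value_counts()
        row = {"treatment": label, "n": n}
        for cat in ("cost", "no_cost", "benefit"):
            row[cat] = int(counts.get(cat, 0))
            row[f"frac_{cat}"] = row[cat] / n if n else np.nan
        row["mean_distance"] = float(cls["distance"].mean()) if n else np.nan
        return row

    rows = [one(grp, t) for t, grp in costs.groupby("treatment", sort=False)]
    rows.append(one(costs, "all"))
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ pipeline helpers


@dataclass
class CostAnalysis:
    line: NoCostLine
    lineages: pd.DataFrame
    treatments: pd.DataFrame


def cost_of_generalization(
    dw: pd.DataFrame,
    line_treatments: tuple[str, str] = ("EH0", "EH80"),
    env_pair: tuple[float, float] = (0.0, 0.8),
    lineage_limit: float = 2.163,
    treatment_limit: float = 0.634,
    entity_treatments: Sequence[str] | None = None,
) -> CostAnalysis:
    """Cost-of-generalization analysis for one chemical's dw table.

    ``dw`` needs columns lineage, treatment, stress_fraction, dw.  The no-cost
    line joins the two constant-treatment mean points in the
    (env_pair[0], env_pair[1]) plane; lineages and treatment means of
    ``entity_treatments`` (default: the fluctuating treatments, identified by
    a two-level schedule naming convention ``EHa_b``; otherwise every
    treatment outside the anchors) are classified by signed orthogonal
    distance.
    """
    wide = (
        dw[dw["stress_fraction"].isin(env_pair)]
        .pivot_table(index=["lineage", "treatment"], columns="stress_fraction", values="dw")
        .reset_index()
    )
    for env in env_pair:
        if env not in wide.columns:
            raise ValueError(f"no fitness changes measured in the {env:.0%} environment")
    wide = wide.rename(columns={env_pair[0]: "x", env_pair[1]: "y"})
    anchors = {}
    for t in line_treatments:
        sub = wide[wide["treatment"] == t]
        if sub.empty:
            raise ValueError(f"treatment {t!r} absent; cannot place the no-cost line")
        anchors[t] = (sub["x"].mean(), sub["y"].mean())
    line = no_cost_line(anchors[line_treatments[0]], anchors[line_treatments[1]])

    if entity_treatments is None:
        non_anchor = [t for t in wide["treatment"].unique() if t not in line_treatments]
        fluct_named = [t for t in non_anchor if "_" in str(t)]
        entity_treatments = fluct_named or non_anchor
    fluct = wide[wide["treatment"].isin(entity_treatments)].copy()
    fluct = fluct.dropna(subset=["x", "y"])
    fluct["distance"] = orthogonal_cost(fluct[["x", "y"]].to_numpy(), line) if len(fluct) else []
    fluct["category"] = classify_cost(fluct["distance"], lineage_limit).values if len(fluct) else []

    trows = []
    for t, grp in fluct.groupby("treatment", sort=False):
        pt = (grp["x"].mean(), grp["y"].mean())
        dist = float(orthogonal_cost([pt], line)[0])
        trows.append((t, pt[0], pt[1], dist, classify_cost([dist], treatment_limit).iloc[0]))
    treatments = pd.DataFrame(trows, columns=["treatment", "x", "y", "distance", "category"])

    return CostAnalysis(line=line, lineages=fluct, treatments=treatments)


def constant_treatment_slopes(
    dw: pd.DataFrame,
    constant_treatments: dict[float, str] | None = None,
) -> pd.DataFrame:
    """Slopes between constant-treatment mean points for every env pair.

    ``constant_treatments`` maps home stress fraction -> treatment name
    (default the study's EH0/EH40/EH80).  For the pair (low, high) the points
    are (mean dw in low env, mean dw in high env) for the treatment evolved at
    ``low`` and the one evolved at ``high``.
    """
    if constant_treatments is None:
        constant_treatments = {0.0: "EH0", 0.4: "EH40", 0.8: "EH80"}
    means = (
        dw[dw["treatment"].isin(constant_treatments.values())]
        .groupby(["treatment", "stress_fraction"])["dw"]
        .mean()
    )
    fracs = sorted(constant_treatments)
    rows = []
    for i, lo in enumerate(fracs):
        for hi in fracs[i + 1 :]:
            ta, tb = constant_treatments[lo], constant_treatments[hi]
            try:
                pa = (means[(ta, lo)], means[(ta, hi)])
                pb = (means[(tb, lo)], means[(tb, hi)])
                res = genetic_correlation_slope(pa, pb, (lo, hi))
                rows.append((lo, hi, ta, tb, res.slope, res.direction))
            except (KeyError, ValueError) as exc:
                logger.warning("slope for envs (%s, %s) unavailable: %s", lo, hi, exc)
                rows.append((lo, hi, ta, tb, np.nan, "undefined"))
    return pd.DataFrame(
        rows, columns=["env_low", "env_high", "treatment_low", "treatment_high", "slope", "direction"]
    )
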