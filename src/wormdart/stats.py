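"""Statistics layer of the DART assay.

Implements the full analysis chain applied to worm-level phenotype tables:
Tukey-fence outlier filtering, per-well aggregation, repeatability CV%
combinatorics, strictly standardized mean difference (SSMD), power analysis
for the 3-replicate design, constrained four-parameter-logistic (4PL)
concentration-response fitting with EC_F point estimates and confidence
intervals, extra-sum-of-squares curve comparison, and endpoint-sensitivity
ordering.

The 4PL model is parameterised in linear concentration,

    y(c) = Bottom + (Top - Bottom) / (1 + (c / EC50)^h),   h > 0,

so the solvent control (c = 0) is fitted naturally at Top.  The lower
asymptote may be fixed to the minimum biologically possible value: 0 for
embryo counts, and L1-larva body dimensions for developmental endpoints
(length 150 um, area 1,500 um2, and the cylinder-model volume 11,775 um3).
EC_F for an F% effect is ``EC50 * (F / (100 - F))^(1/h)``; its confidence
interval is an asymptotic Wald interval on the log scale via the delta
method.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ENDPOINTS",
    "fourpl",
    "tukey_filter",
    "well_means",
    "cv_percent",
    "combo_cv_analysis",
    "RepeatabilityResult",
    "ssmd",
    "SSMDResult",
    "power_one_sample",
    "power_min_effect",
    "PowerCurve",
    "oneway_anova",
    "fit_4pl",
    "FourPLFit",
    "ec_f",
    "ECEstimate",
    "compare_fits",
    "normalize_response",
    "normalize_and_rank",
    "p_stars",
    "l1_cylinder_volume",
    "l1_bottom_constraints",
    "UnidentifiableFitError",
]

ENDPOINTS = (
    "length_um", "area_um2", "volume_um3",
    "early_count", "late_count", "total_count",
)


class UnidentifiableFitError(RuntimeError):
    """4PL fit did not converge to an identifiable concentration response."""


# ---------------------------------------------------------------------------
# outlier filtering and aggregation


def tukey_filter(
    worms: pd.DataFrame,
    endpoints: Sequence[str] = ("volume_um3", "total_count"),
    k: float = 1.5,
    group_cols: Sequence[str] = ("experiment", "well"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove per-well outliers outside Tukey fences (Q1/Q3 -/+ k*IQR).

    Quartiles use linear interpolation of order statistics.  A worm is
    excluded if *any* listed endpoint lies strictly outside the inclusive
    fences (OR rule — debris typically distorts volume or embryo count).
    Groups with fewer than 4 worms pass through unfiltered with a warning.
    Returns (kept, excluded); the excluded table carries an
    ``outlier_endpoints`` column naming the offending endpoint(s).
    """
    kept_parts, excl_parts = [], []
    for key, grp in worms.groupby(list(group_cols), sort=False):
        if len(grp) < 4:
            warnings.warn(f"group {key}: fewer than 4 worms, passed unfiltered")
            kept_parts.append(grp)
            continue
        bad = pd.Series([""] * len(grp), index=grp.index)
        for ep in endpoints:
            vals = grp[ep].astype(float)
            q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            out = (vals < lo) | (vals > hi)
            bad[out] += ep + ";"
        excl = grp[bad != ""].copy()
        if len(excl):
            excl["outlier_endpoints"] = bad[bad != ""].str.rstrip(";")
            excl_parts.append(excl)
        kept_parts.append(grp[bad == ""])
    kept = pd.concat(kept_parts) if kept_parts else worms.iloc[0:0]
    excluded = (
        pd.concat(excl_parts)
        if excl_parts
        else worms.iloc[0:0].assign(outlier_endpoints=pd.Series(dtype=str))
    )
    return kept, excluded


def well_means(
    kept: pd.DataFrame,
    endpoints: Sequence[str] = ENDPOINTS,
    group_cols: Sequence[str] = ("experiment", "well"),
    n_before: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-well arithmetic endpoint means with worm counts.

    Carries condition/concentration columns through when present.  Wells
    emptied by filtering appear with ``n_after = 0`` and NaN means when
    ``n_before`` (a Series indexed by the group key) is supplied.
    """
    if len(kept) == 0 and n_before is None:
        raise ValueError("kept table is empty")
    eps = [e for e in endpoints if e in kept.columns]
    agg = kept.groupby(list(group_cols), sort=False)[eps].mean().reset_index()
    counts = kept.groupby(list(group_cols), sort=False).size().rename("n_after").reset_index()
    out = agg.merge(counts, on=list(group_cols))
    for extra in ("condition", "concentration_uM", "chemical", "replicate"):
        if extra in kept.columns:
            m = kept.groupby(list(group_cols), sort=False)[extra].first().reset_index()
            out = out.merge(m, on=list(group_cols))
    if n_before is not None:
        nb = n_before.rename("n_before").reset_index()
        out = nb.merge(out, on=list(group_cols), how="left")
        out["n_after"] = out["n_after"].fillna(0).astype(int)
        out["emptied"] = out["n_after"] == 0
    return out


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


@dataclass
class RepeatabilityResult:
    """CV% over all k-subsets of replicates, pooled across well positions."""

    endpoint: str
    condition: str
    cvs: list  # one CV% per (well position, replicate subset)
    k: int
    n_replicates: int
    per_position: dict = field(default_factory=dict)

    @property
    def mean_cv(self) -> float:
        return float(np.mean(self.cvs))

    @property
    def sem_cv(self) -> float | None:
        if len(self.cvs) < 2:
            return None
        return float(np.std(self.cvs, ddof=1) / math.sqrt(len(self.cvs)))

    @property
    def combinations_per_position(self) -> int:
        return math.comb(self.n_replicates, self.k)


def combo_cv_analysis(
    wells: pd.DataFrame,
    endpoints: Sequence[str] = ENDPOINTS,
    k: int = 3,
    replicate_col: str = "experiment",
    position_col: str = "well",
    condition_col: str | None = "condition",
) -> list[RepeatabilityResult]:
    """Inter-replicate repeatability: CV% of every k-subset of replicates.

    For each well position present in ``n >= k`` replicates, the CV% of the
    k corresponding well means is computed for every one of the C(n, k)
    replicate subsets (n = 5, k = 3 gives 10 combinations per position);
    results are pooled across the positions of each condition and reported
    as mean +/- SEM (per-position lists are kept as well).  A position with
    exactly k replicates yields one combination and an undefined SEM.
    """
    results = []
    if condition_col is not None and condition_col in wells.columns:
        cond_groups = wells.groupby(condition_col, sort=False)
    else:
        cond_groups = [("all", wells)]
    for ep in endpoints:
        if ep not in wells.columns:
            continue
        for cond, cgrp in cond_groups:
            cvs, per_pos = [], {}
            for pos, pgrp in cgrp.groupby(position_col, sort=False):
                reps = pgrp.sort_values(replicate_col)
                n = len(reps)
                if n < k:
                    raise ValueError(
                        f"well position {pos}: {n} replicates < subset size {k}"
                    )
                vals = reps[ep].to_numpy(dtype=float)
                pos_cvs = []
                for combo in itertools.combinations(range(n), k):
                    sub = vals[list(combo)]
                    if sub.mean() == 0 or np.any(np.isnan(sub)):
                        continue  # fully suppressed endpoint: CV undefined
                    pos_cvs.append(cv_percent(sub))
                per_pos[pos] = pos_cvs
                cvs.extend(pos_cvs)
            if not cvs:
                continue
            results.append(RepeatabilityResult(
                endpoint=ep, condition=str(cond), cvs=cvs, k=k,
                n_replicates=int(cgrp.groupby(position_col)[replicate_col].nunique().iloc[0]),
                per_position=per_pos,
            ))
    return results


# ---------------------------------------------------------------------------
# effect size, power, ANOVA


@dataclass(frozen=True)
class SSMDResult:
    value: float
    quality: str  # excellent (>= 3), good (2..3), weak (< 2)
    infinite_separation: bool = False


def ssmd(control: Sequence[float], treated: Sequence[float]) -> SSMDResult:
    """Strictly standardized mean difference, oriented so reductions are positive.

    Method-of-moments estimator with sample SDs:
    ``(mean_control - mean_treated) / sqrt(SD_c^2 + SD_t^2)``.  Values >= 3
    indicate excellent and 2-3 good assay separation.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if len(c) < 2 or len(t) < 2:
        raise ValueError("need >= 2 values per group")
    denom = math.sqrt(c.var(ddof=1) + t.var(ddof=1))
    if denom == 0:
        diff = c.mean() - t.mean()
        value = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        quality = "excellent" if value > 0 else "weak"
        return SSMDResult(value, quality, infinite_separation=diff != 0)
    value = (c.mean() - t.mean()) / denom
    quality = "excellent" if value >= 3 else ("good" if value >= 2 else "weak")
    return SSMDResult(float(value), quality)


@dataclass
class PowerCurve:
    control_mean: float
    control_sd: float
    n: int
    alpha: float
    one_tailed: bool
    effects: np.ndarray  # effect fractions below the control mean
    power: np.ndarray
    min_detectable_effect: float | None  # smallest effect with power >= 0.80

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"effect_fraction": self.effects, "power": self.power})


def power_one_sample(
    effect_fraction: float | np.ndarray,
    mean: float,
    sd: float,
    n: int = 3,
    alpha: float = 0.05,
) -> np.ndarray:
    """Power of a one-sample, one-tailed t test to detect a fractional reduction.

    The treated-group mean sits ``effect_fraction * mean`` below the control
    mean; noncentrality is ``sqrt(n) * effect * mean / sd`` with df = n - 1.
    An effect of 0 returns alpha exactly.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    eff = np.asarray(effect_fraction, dtype=float)
    ncp = math.sqrt(n) * eff * mean / sd
    tcrit = sps.t.ppf(1 - alpha, n - 1)
    return sps.nct.sf(tcrit, n - 1, ncp)


def power_min_effect(
    control_mean: float,
    control_sd: float,
    n: int = 3,
    alpha: float = 0.05,
    effect_grid: Sequence[float] | None = None,
    target_power: float = 0.80,
) -> PowerCurve:
    """Power across a grid of hypothetical reductions below the control mean.

    Defaults to the 2.5%-50% grid used for assay design; the minimum
    detectable effect is the smallest (linearly interpolated) effect
    reaching ``target_power``.
    """
    if effect_grid is None:
        effect_grid = np.arange(0.025, 0.5001, 0.025)
    eff = np.asarray(effect_grid, dtype=float)
    power = np.asarray(power_one_sample(eff, control_mean, control_sd, n, alpha))
    mde = None
    if np.any(power >= target_power):
        i = int(np.argmax(power >= target_power))
        if i == 0:
            mde = float(eff[0])
        else:
            p0, p1 = power[i - 1], power[i]
            mde = float(eff[i - 1] + (target_power - p0) / (p1 - p0) * (eff[i] - eff[i - 1]))
    return PowerCurve(control_mean, control_sd, n, alpha, True, eff, power, mde)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition) -> (F, p)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs >= 2 values")
    flat = np.concatenate(arrs)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrs)
    if not np.isfinite(f):  # zero within-group variance
        return float("inf"), 0.0
    return float(f), float(p)


def p_stars(p: float) -> str:
    """Significance stars: ns >= 0.05, * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# 4PL fitting


def fourpl(
    c: float | np.ndarray, top: float, bottom: float, ec50: float, hill: float
) -> float | np.ndarray:
    """Four-parameter logistic, decreasing for hill > 0; y(0) = top exactly."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        # evaluate (c/ec50)^hill on the log scale, clipped to avoid overflow
        log_ratio = np.where(c > 0, hill * (np.log(np.where(c > 0, c, 1.0)) - math.log(ec50)), -np.inf)
    ratio = np.exp(np.clip(log_ratio, -745.0, 709.0))
    y = bottom + (top - bottom) / (1.0 + ratio)
    return float(y) if y.ndim == 0 else y


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with asymptotic covariance on the internal scale.

    Internal free-parameter order: (top[, bottom], log_ec50, log_hill);
    ``bottom`` is absent when fixed.  ``cov`` is the Jacobian-based
    covariance of the free parameters at the optimum.
    """

    top: float
    bottom: float
    log_ec50: float
    log_hill: float
    bottom_fixed: bool
    cov: np.ndarray | None
    ssr: float
    dof: int
    n: int
    converged: bool
    param_names: tuple[str, ...]

    @property
    def ec50(self) -> float:
        return math.exp(self.log_ec50)

    @property
    def hill(self) -> float:
        return math.exp(self.log_hill)

    def predict(self, c):
        return fourpl(c, self.top, self.bottom, self.ec50, self.hill)

    def _index(self, name: str) -> int:
        return self.param_names.index(name)


def _pack_model(bottom_fixed, bottom_value):
    def unpack(theta):
        if bottom_fixed:
            top, le, lh = theta
            return top, bottom_value, le, lh
        top, bot, le, lh = theta
        return top, bot, le, lh
    return unpack


def _fit_once(c, y, theta0, bottom_fixed, bottom_value):
    unpack = _pack_model(bottom_fixed, bottom_value)

    def resid(theta):
        top, bot, le, lh = unpack(theta)
        return fourpl(c, top, bot, math.exp(le), math.exp(lh)) - y

    try:
        res = optimize.least_squares(
            resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000,
        )
    except Exception:
        return None
    return res


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    bottom: float | str = "free",
    ec50_bounds_factor: float = 100.0,
) -> FourPLFit:
    """Least-squares 4PL fit of well means vs concentration.

    ``bottom`` is either ``"free"`` or a fixed value (the biological minimum
    constraint).  Deterministic multi-start initialisation: a log-spaced
    EC50 grid spanning the positive concentration range crossed with Hill
    slopes {0.5, 1, 2, 4}; the best sum of squares wins.  Raises
    :class:`UnidentifiableFitError` when no start converges, the response
    carries no signal, or the fitted EC50 falls outside
    ``[min_positive_c / f, max_c * f]``.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentration/response length mismatch")
    if len(np.unique(c)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    bottom_fixed = not (isinstance(bottom, str) and bottom == "free")
    bottom_value = float(bottom) if bottom_fixed else 0.0
    n_params = 3 if bottom_fixed else 4
    if len(c) < n_params + 1:
        raise ValueError("fewer points than parameters + 1")
    if np.ptp(y) == 0:
        raise UnidentifiableFitError("constant response: no concentration effect")

    pos = np.sort(np.unique(c[c > 0]))
    top0 = float(np.mean(y[c == c.min()]))
    bot0 = bottom_value if bottom_fixed else float(min(np.mean(y[c == c.max()]), top0))
    ec_grid = np.geomspace(pos[0], pos[-1], 5)
    best, best_ssr = None, math.inf
    for e0 in ec_grid:
        for h0 in (0.5, 1.0, 2.0, 4.0):
            theta0 = (
                [top0, math.log(e0), math.log(h0)]
                if bottom_fixed
                else [top0, bot0, math.log(e0), math.log(h0)]
            )
            res = _fit_once(c, y, theta0, bottom_fixed, bottom_value)
            if res is None or not res.success:
                continue
            ssr = float(2 * res.cost)
            if ssr < best_ssr:
                best, best_ssr = res, ssr
    if best is None:
        raise UnidentifiableFitError("no start converged")
    unpack = _pack_model(bottom_fixed, bottom_value)
    top, bot, le, lh = unpack(best.x)
    ec50 = math.exp(le)
    if not (pos[0] / ec50_bounds_factor <= ec50 <= pos[-1] * ec50_bounds_factor):
        raise UnidentifiableFitError(
            f"EC50 {ec50:.3g} outside the identifiable range"
        )
    dof = len(c) - n_params
    ssr = float(2 * best.cost)
    cov = None
    if dof > 0:
        J = best.jac
        try:
            jtj_inv = np.linalg.inv(J.T @ J)
            cov = jtj_inv * (ssr / dof)
        except np.linalg.LinAlgError:
            cov = None
    names = ("top", "log_ec50", "log_hill") if bottom_fixed else (
        "top", "bottom", "log_ec50", "log_hill")
    return FourPLFit(
        top=float(top), bottom=float(bot), log_ec50=float(le), log_hill=float(lh),
        bottom_fixed=bottom_fixed, cov=cov, ssr=ssr, dof=dof, n=len(c),
        converged=True, param_names=names,
    )


@dataclass(frozen=True)
class ECEstimate:
    F: float
    value: float
    ci_low: float
    ci_high: float


def ec_f(fit: FourPLFit, F: float, confidence: float = 0.95) -> ECEstimate:
    """Concentration producing an F% effect: ``EC50 * (F/(100-F))^(1/h)``.

    The confidence interval is a Wald interval on log EC_F via the delta
    method (gradient [1, -L/h] w.r.t. (log EC50, log h), L = ln(F/(100-F))),
    using a t quantile at the fit's residual degrees of freedom.
    """
    if not (0 < F < 100):
        raise ValueError("F must be in (0, 100)")
    L = math.log(F / (100.0 - F))
    log_ecf = fit.log_ec50 + L / fit.hill
    value = math.exp(log_ecf)
    if fit.cov is None or fit.dof <= 0:
        return ECEstimate(F, value, math.nan, math.nan)
    i_e, i_h = fit._index("log_ec50"), fit._index("log_hill")
    grad = np.zeros(len(fit.param_names))
    grad[i_e] = 1.0
    grad[i_h] = -L / fit.hill
    var = float(grad @ fit.cov @ grad)
    var = max(var, 0.0)
    tq = sps.t.ppf(0.5 + confidence / 2.0, fit.dof)
    half = tq * math.sqrt(var)
    return ECEstimate(F, value, math.exp(log_ecf - half), math.exp(log_ecf + half))


def compare_fits(
    data_a: tuple[Sequence[float], Sequence[float]],
    data_b: tuple[Sequence[float], Sequence[float]],
    shared: Sequence[str] = ("log_ec50", "log_hill"),
    bottom: float | str = "free",
) -> tuple[float, float]:
    """Extra-sum-of-squares F test for parameter equality between two curves.

    The separate model fits each dataset independently; the shared model
    forces the listed parameters (among top, bottom, log_ec50, log_hill)
    equal across datasets.  ``F = ((SS_sh - SS_sep)/(df_sh - df_sep)) /
    (SS_sep/df_sep)`` with p from the F distribution.
    """
    fit_a = fit_4pl(*data_a, bottom=bottom)
    fit_b = fit_4pl(*data_b, bottom=bottom)
    ss_sep = fit_a.ssr + fit_b.ssr
    df_sep = fit_a.dof + fit_b.dof
    if df_sep <= 0:
        raise ValueError("fewer points than parameters + 1")

    bottom_fixed = not (isinstance(bottom, str) and bottom == "free")
    bottom_value = float(bottom) if bottom_fixed else 0.0
    per_dataset = [p for p in fit_a.param_names if p not in shared]
    shared = [p for p in fit_a.param_names if p in shared]
    names = shared + [f"{p}_a" for p in per_dataset] + [f"{p}_b" for p in per_dataset]

    ca, ya = (np.asarray(v, dtype=float) for v in data_a)
    cb, yb = (np.asarray(v, dtype=float) for v in data_b)

    def split(theta):
        vals = dict(zip(names, theta))
        def params(suffix, ref):
            d = {}
            for p in fit_a.param_names:
                d[p] = vals[p] if p in shared else vals[f"{p}_{suffix}"]
            top = d["top"]
            bot = bottom_value if bottom_fixed else d["bottom"]
            return top, bot, math.exp(d["log_ec50"]), math.exp(d["log_hill"])
        return params("a", fit_a), params("b", fit_b)

    def resid(theta):
        pa, pb = split(theta)
        return np.concatenate([fourpl(ca, *pa) - ya, fourpl(cb, *pb) - yb])

    def get(fit, p):
        return {"top": fit.top, "bottom": fit.bottom,
                "log_ec50": fit.log_ec50, "log_hill": fit.log_hill}[p]

    theta0 = [0.5 * (get(fit_a, p) + get(fit_b, p)) for p in shared]
    theta0 += [get(fit_a, p) for p in per_dataset]
    theta0 += [get(fit_b, p) for p in per_dataset]
    res = optimize.least_squares(resid, theta0, method="lm",
                                 xtol=1e-14, ftol=1e-14, max_nfev=5000)
    ss_sh = float(2 * res.cost)
    n_total = len(ca) + len(cb)
    df_sh = n_total - len(names)
    if df_sh <= df_sep:
        raise ValueError("shared model not nested below separate model")
    num = max(ss_sh - ss_sep, 0.0) / (df_sh - df_sep)
    den = ss_sep / df_sep
    if den == 0:
        return (0.0, 1.0) if num == 0 else (math.inf, 0.0)
    F = num / den
    p = float(sps.f.sf(F, df_sh - df_sep, df_sep))
    return float(F), p


# ---------------------------------------------------------------------------
# normalisation and endpoint ordering


def normalize_response(y, top: float, bottom: float):
    """Rescale so the control (top) maps to 100% and the bottom constraint to 0%."""
    return (np.asarray(y, dtype=float) - bottom) / (top - bottom) * 100.0


def normalize_and_rank(
    fits: dict[str, FourPLFit],
    F: float = 10.0,
) -> pd.DataFrame:
    """Sort endpoints by EC_F sensitivity with CI-overlap flags.

    Each endpoint's response scale is normalised (control = 100%, bottom
    constraint = 0%); endpoints are ordered by ascending EC_F (most
    sensitive first).  ``ci_overlaps_next`` flags pairs whose 95% CIs
    overlap, i.e. whose sensitivity ordering is not resolved.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 endpoint fits to rank")
    rows = []
    for ep, fit in fits.items():
        est = ec_f(fit, F)
        rows.append({
            "endpoint": ep, "ec_f": est.value,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "ec50": fit.ec50, "hill": fit.hill,
            "top_pct": 100.0,
            "bottom_pct": normalize_response(fit.bottom, fit.top, fit.bottom),
        })
    out = pd.DataFrame(rows).sort_values("ec_f").reset_index(drop=True)
    overlaps = []
    for i in range(len(out)):
        if i == len(out) - 1:
            overlaps.append(False)
            continue
        hi = out.loc[i, "ci_high"]
        lo_next = out.loc[i + 1, "ci_low"]
        overlaps.append(bool(np.isfinite(hi) and np.isfinite(lo_next) and hi >= lo_next))
    out["ci_overlaps_next"] = overlaps
    out["F"] = F
    return out


# ---------------------------------------------------------------------------
# biological bottom constraints


def l1_cylinder_volume(length_um: float = 150.0, area_um2: float = 1500.0,
                       pi: float = 3.14) -> float:
    """Volume of an L1 larva under the cylinder model.

    A cylinder of length L with projected area A has width A/L (= diameter),
    so V = pi * (A / (2L))^2 * L.  With the conventional L1 dimensions
    (150 um, 1,500 um2) and pi = 3.14 this gives 11,775 um3, the lower
    asymptote used for the developmental volume endpoint.
    """
    radius = area_um2 / length_um / 2.0
    return pi * radius**2 * length_um


def l1_bottom_constraints() -> dict[str, float]:
    """Minimum biologically possible endpoint values (lower 4PL asymptotes)."""
    return {
        "length_um": 150.0,
        "area_um2": 1500.0,
        "volume_um3": l1_cylinder_volume(),
        "early_count": 0.0,
        "late_count": 0.0,
        "total_count": 0.0,
    }
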