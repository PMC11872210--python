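"""Box-Cox transformation, factorial and one-way ANOVA with Tukey HSD,
assumption checks, and relative-change summaries.

The factorial model is the three-way fixed-effects ANOVA
``response ~ cytotype * (water * co2)`` with sequential (type I) sums of
squares.  The experiment is near-balanced, so term order barely
matters, but sequential SS is the documented convention here.
Responses are aggregated to one mean per individual x treatment cell
before fitting (pots are technical replicates of a donor individual,
not independent units), and Box-Cox transformed per response when
normality requires it.  Normality of residuals is checked with
Shapiro-Wilk and variance homogeneity with the median-centered Levene
(Brown-Forsythe) test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .synth import FUNCTIONAL_TRAITS


@dataclass
class TransformSpec:
    """A fitted Box-Cox power transform: (y^lambda - 1)/lambda, with the
    lambda -> 0 limit log(y).  Requires strictly positive responses."""

    lmbda: float
    method: str = "profile-likelihood ML"
    log_likelihood: float | None = None

    def apply(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise ValueError("Box-Cox requires strictly positive responses")
        if abs(self.lmbda) < 1e-6:
            return np.log(y)
        return (y ** self.lmbda - 1.0) / self.lmbda

    def invert(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if abs(self.lmbda) < 1e-6:
            return np.exp(z)
        return (self.lmbda * z + 1.0) ** (1.0 / self.lmbda)


def _boxcox_llf_grid(lams: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox exponent, vectorized over a
    grid (agrees with ``scipy.stats.boxcox_llf`` at every point)."""
    n = len(y)
    logy = np.log(y)
    out = np.empty(len(lams))
    for k, lam in enumerate(lams):
        z = logy if abs(lam) < 1e-6 else (y ** lam - 1.0) / lam
        out[k] = (lam - 1.0) * logy.sum() - n / 2.0 * np.log(z.var())
    return out


def boxcox(y, lmbda: float | None = None,
           grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
           ) -> tuple[TransformSpec, np.ndarray]:
    """Estimate lambda by profile maximum likelihood and transform.

    The profile log-likelihood is evaluated on a grid (default
    [-2, 2] in steps of 0.01) and the maximum refined by fitting a
    parabola through the best grid point and its neighbours.  Pass
    ``lmbda`` to fix the exponent instead of estimating it.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y must be a 1-D array with at least 2 values")
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive responses")
    if lmbda is None:
        lo, hi, step = grid
        lams = np.arange(lo, hi + step / 2, step)
        llf = _boxcox_llf_grid(lams, y)
        i = int(np.argmax(llf))
        lmbda = float(lams[i])
        if 0 < i < len(lams) - 1:
            # quadratic refinement through the three best points
            x0, x1, x2 = lams[i - 1], lams[i], lams[i + 1]
            f0, f1, f2 = llf[i - 1], llf[i], llf[i + 1]
            denom = (f0 - 2.0 * f1 + f2)
            if denom < 0:
                lmbda = float(x1 - step * (f2 - f0) / (2.0 * denom))
    spec = TransformSpec(
        lmbda=float(lmbda),
        log_likelihood=float(_boxcox_llf_grid(np.asarray([lmbda]), y)[0]))
    return spec, spec.apply(y)


@dataclass
class AnovaResult:
    """ANOVA table with optional post-hoc and assumption checks.

    ``table`` has one row per model term plus ``Residual`` with columns
    ``sum_sq``, ``df``, ``F`` and ``PR(>F)`` (sequential SS).
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    assumptions: dict = field(default_factory=dict)
    transform: TransformSpec | None = None
    nobs: int = 0

    def term_pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def _aggregate_records(records: pd.DataFrame, response: str) -> pd.DataFrame:
    """Mean response per surviving individual x treatment cell."""
    data = records[records["survived"]] if "survived" in records else records
    data = data.dropna(subset=[response])
    grouped = (data.groupby(["individual", "cytotype", "water", "co2"],
                            observed=True)[response]
               .mean().reset_index())
    return grouped


def factorial_anova(records: pd.DataFrame, response: str,
                    transform: TransformSpec | str | None = None,
                    aggregate: bool = True,
                    posthoc: bool = True) -> AnovaResult:
    """Three-way factorial ANOVA ``response ~ cytotype * (water * co2)``.

    ``transform`` may be a fitted :class:`TransformSpec`, the string
    ``"boxcox"`` (estimate lambda on this response), or None.  With
    ``aggregate=True`` (default) pots are first averaged per individual
    and treatment cell.  Sequential (type I) sums of squares.
    """
    data = _aggregate_records(records, response) if aggregate else \
        records.dropna(subset=[response]).copy()
    if len(data) == 0:
        raise ValueError("no usable observations")
    for factor in ("cytotype", "water", "co2"):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")

    cells = data.groupby(["cytotype", "water", "co2"], observed=True).size()
    n_cells = (data["cytotype"].nunique() * data["water"].nunique()
               * data["co2"].nunique())
    if len(cells) < n_cells:
        warnings.warn("design has empty cells; sequential SS are order-dependent")

    spec: TransformSpec | None = None
    y = data[response].to_numpy(dtype=float)
    if transform == "boxcox":
        spec, y = boxcox(y)
    elif isinstance(transform, TransformSpec):
        spec = transform
        y = spec.apply(y)
    data = data.assign(_y=y)

    n = len(data)
    n_params = (data["cytotype"].nunique() * data["water"].nunique()
                * data["co2"].nunique())
    if n - n_params < 1:
        raise ValueError("zero residual degrees of freedom")

    model = smf.ols("_y ~ C(cytotype) * (C(water) * C(co2))", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index=lambda s: s.strip())

    checks = assumption_checks(
        model.resid.to_numpy(),
        groups=[g["_y"].to_numpy() for _, g in
                data.groupby(["cytotype", "water", "co2"], observed=True)
                if len(g) >= 2])

    hsd = None
    if posthoc:
        labels = (data["cytotype"].astype(str) + ":" + data["water"].astype(str)
                  + ":" + data["co2"].astype(str))
        hsd = tukey_hsd(data["_y"].to_numpy(), labels.to_numpy())
    return AnovaResult(table=table, posthoc=hsd, assumptions=checks,
                       transform=spec, nobs=n)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values.

    Uses the exact studentized-range distribution with the Tukey-Kramer
    allowance for unequal group sizes.  Groups with no observations are
    dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    samples, kept = [], []
    for g in labels:
        v = values[groups == g]
        if len(v) == 0:
            warnings.warn(f"group {g!r} has no observations; excluded")
            continue
        samples.append(v)
        kept.append(g)
    if len(kept) < 2:
        raise ValueError("need at least two non-empty groups")
    res = stats.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i, j in itertools.combinations(range(len(kept)), 2):
        rows.append({
            "group1": kept[i], "group2": kept[j],
            "meandiff": float(samples[i].mean() - samples[j].mean()),
            "p_adj": float(np.clip(res.pvalue[i, j], 0.0, 1.0)),
            "lower": float(ci.low[i, j]), "upper": float(ci.high[i, j]),
            "reject": bool(res.pvalue[i, j] < alpha),
        })
    return pd.DataFrame(rows)


def assumption_checks(residuals, groups: Sequence[np.ndarray] | None = None
                      ) -> dict:
    """Shapiro-Wilk normality of residuals and median-centered Levene
    (Brown-Forsythe) homogeneity across groups."""
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw = stats.shapiro(residuals)
    out = {"shapiro_w": float(sw.statistic), "shapiro_p": float(sw.pvalue)}
    if groups is not None and len(groups) >= 2:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lv = stats.levene(*groups, center="median")
        stat = float(lv.statistic)
        out["levene_stat"] = 0.0 if np.isnan(stat) else stat
        out["levene_p"] = float(lv.pvalue)
    return out


def one_way_anova(index_values: Mapping[str, Sequence[float]],
                  posthoc: bool = True) -> AnovaResult:
    """One-way ANOVA across groups (used to compare plasticity indices
    among individuals, df = k-1, or between cytotypes, df = 1)."""
    if len(index_values) < 2:
        raise ValueError("need at least two groups")
    frames = []
    for g, vals in index_values.items():
        vals = np.asarray(vals, dtype=float)
        frames.append(pd.DataFrame({"group": str(g), "_y": vals}))
    data = pd.concat(frames, ignore_index=True).dropna(subset=["_y"])
    if data["group"].nunique() < 2:
        raise ValueError("need at least two non-empty groups")
    if len(data) - data["group"].nunique() < 1:
        raise ValueError("zero residual degrees of freedom")
    model = smf.ols("_y ~ C(group)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index=lambda s: s.strip())
    hsd = tukey_hsd(data["_y"].to_numpy(), data["group"].to_numpy()) \
        if posthoc else None
    checks = assumption_checks(
        model.resid.to_numpy(),
        groups=[g["_y"].to_numpy() for _, g in data.groupby("group")
                if len(g) >= 2]) if len(data) >= 3 else {}
    return AnovaResult(table=table, posthoc=hsd, assumptions=checks, nobs=len(data))


def relative_decrease(reference_mean: float, treatment_mean: float) -> int:
    """Percent change of a treatment mean relative to a reference mean
    (the reference is 100%), rounded to the nearest integer percent."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    pct = 100.0 * (treatment_mean - reference_mean) / reference_mean
    return int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5))
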