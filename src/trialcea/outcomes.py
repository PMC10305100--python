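"""Economic endpoints: LOCF imputation, quality-of-life utilities and QALYs,
and covariate-adjusted arm effects.

The two endpoints are the post-intervention PHQ-9 depression score (exposed
both on its native scale, lower = better, and on the sign-flipped reduction
scale, higher = better) and the 12-month quality-adjusted life year (QALY)
accumulated from a utility trajectory. Utilities derive from the 26-item
WHOQOL-BREF: items are scored into the four standard domains (0-100), then
mapped to a single [0, 1] utility. The exact published domain-to-utility
conversion is not reproducible from public sources, so the mapping is a
pluggable strategy; the default is the equal-weight linear stand-in
(mean of the four domain scores / 100), which is monotone in every domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .costing import SERVICE_CATEGORIES
from .simulate import REVERSE_ITEMS, TrialDataset

__all__ = [
    "AdjustedEffect",
    "locf_impute",
    "bref_to_domains",
    "domains_to_utility",
    "utility_trajectories",
    "qaly_12m",
    "endpoint_table",
    "adjusted_effect",
    "SingularModelError",
]

#: WHOQOL-BREF domain composition (1-indexed item numbers). Items 1 and 2
#: (overall quality of life / general health) enter no domain.
DOMAIN_ITEMS = {
    "physical": (3, 4, 10, 15, 16, 17, 18),
    "psychological": (5, 6, 7, 11, 19, 26),
    "social": (20, 21, 22),
    "environment": (8, 9, 12, 13, 14, 23, 24, 25),
}

ENDPOINTS = ("phq9", "qaly")


class SingularModelError(RuntimeError):
    """Raised when the adjustment design matrix is singular."""


def locf_impute(dataset: TrialDataset) -> TrialDataset:
    """Impute monotone dropout by carrying each participant's last observed
    occasion forward.

    Observed cells are untouched; every imputed cell equals the
    participant's most recent observed value of that variable. Adds an
    ``imputed`` column. Applying the operation twice equals applying it
    once. Raises if any participant is unobserved at baseline or the
    missingness pattern is not monotone.
    """
    df = dataset.data.sort_values(["pid", "week"], kind="stable").reset_index(drop=True)
    obs = df.pivot(index="pid", columns="week", values="observed").astype(bool)
    if not obs.iloc[:, 0].all():
        bad = obs.index[~obs.iloc[:, 0]].tolist()
        raise ValueError(f"participants unobserved at baseline: {bad}")
    arr = obs.to_numpy()
    if arr.shape[1] > 1 and np.any(arr[:, 1:] & ~arr[:, :-1]):
        raise ValueError("missingness is not monotone; LOCF is ambiguous")

    out = df.copy()
    value_cols = dataset.value_columns
    mask = ~out["observed"].to_numpy()
    out.loc[mask, value_cols] = np.nan
    out[value_cols] = out.groupby("pid", sort=False)[value_cols].ffill()
    if "imputed" in out.columns:  # re-application keeps earlier flags
        out["imputed"] = out["imputed"].to_numpy() | mask
    else:
        out["imputed"] = mask
    out["observed"] = True
    return TrialDataset(data=out, design=dataset.design, params=dataset.params)


def bref_to_domains(items) -> pd.DataFrame:
    """Score 26 WHOQOL-BREF item responses into the four 0-100 domains.

    Items 3, 4 and 26 are reverse-scored (``6 - response``); each domain is
    the mean of its scored items times 4 (the 4-20 scale), linearly mapped
    to 0-100. Accepts an (n, 26) array or a DataFrame with columns
    ``item_01..item_26``.
    """
    if isinstance(items, pd.DataFrame):
        cols = [f"item_{i:02d}" for i in range(1, 27)]
        arr = items[cols].to_numpy(dtype=float)
        index = items.index
    else:
        arr = np.atleast_2d(np.asarray(items, dtype=float))
        index = None
    if arr.shape[-1] != 26:
        raise ValueError(f"expected 26 items, got {arr.shape[-1]}")
    valid = np.isnan(arr) | ((arr >= 1) & (arr <= 5) & (arr == np.round(arr)))
    if not valid.all():
        raise ValueError("item responses must be integers in 1..5")
    scored = arr.copy()
    for i in REVERSE_ITEMS:
        scored[:, i - 1] = 6 - scored[:, i - 1]
    out = {}
    for name, idx in DOMAIN_ITEMS.items():
        dom = scored[:, [i - 1 for i in idx]].mean(axis=1) * 4.0
        out[name] = (dom - 4.0) * (100.0 / 16.0)
    return pd.DataFrame(out, index=index)


def domains_to_utility(domains, weights: Sequence[float] | None = None) -> np.ndarray:
    """Map the four 0-100 domain scores to a [0, 1] utility.

    Default: equal-weight mean of the domains divided by 100 — a documented
    stand-in for a published value-set conversion, monotone non-decreasing
    in every domain. ``weights`` (non-negative, summing to 1) swap in an
    alternative linear mapping.
    """
    if isinstance(domains, pd.DataFrame):
        arr = domains[list(DOMAIN_ITEMS)].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(domains, dtype=float))
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 100:
        raise ValueError("domain scores must lie in [0, 100]")
    if weights is None:
        w = np.full(4, 0.25)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be 4 non-negative values summing to 1")
    return arr @ w / 100.0


UtilityMap = Callable[[pd.DataFrame], np.ndarray]


def utility_trajectories(
    dataset: TrialDataset, utility_map: UtilityMap | None = None
) -> pd.DataFrame:
    """Participant x occasion utilities from the quality-of-life items.

    Returns a wide DataFrame indexed by pid with one column per occasion
    week. Requires complete items (run LOCF first under dropout).
    """
    df = dataset.data
    domains = bref_to_domains(df)
    if utility_map is None:
        util = domains_to_utility(domains)
    else:
        util = np.asarray(utility_map(domains), dtype=float)
        if np.nanmin(util) < 0 or np.nanmax(util) > 1:
            raise ValueError("utility mapping produced values outside [0, 1]")
    tall = pd.DataFrame({"pid": df["pid"], "week": df["week"], "utility": util})
    return tall.pivot(index="pid", columns="week", values="utility")


def qaly_12m(
    utilities,
    weeks: Sequence[float],
    horizon_weeks: float = 52.0,
    method: str = "trapezoid",
) -> np.ndarray:
    """Quality-adjusted life years over a 12-month horizon.

    Area under the utility curve across the measurement occasions, with the
    last value carried flat to ``horizon_weeks``, divided by the horizon.
    ``method="trapezoid"`` (default) interpolates linearly between
    occasions; ``method="step"`` holds each value constant until the next
    occasion.
    """
    u = np.atleast_2d(np.asarray(utilities, dtype=float))
    w = np.asarray(weeks, dtype=float)
    if u.shape[-1] != w.size:
        raise ValueError("utilities and weeks have mismatched lengths")
    if np.nanmin(u) < 0 or np.nanmax(u) > 1:
        raise ValueError("utilities must lie in [0, 1]")
    if method == "trapezoid":
        area = np.trapezoid(u, w, axis=-1)
    elif method == "step":
        area = (u[:, :-1] * np.diff(w)).sum(axis=-1)
    else:
        raise ValueError(f"unknown QALY method {method!r}")
    area = area + u[:, -1] * (horizon_weeks - w[-1])
    return area / horizon_weeks


def endpoint_table(
    dataset: TrialDataset,
    endpoint: str,
    utility_map: UtilityMap | None = None,
    qaly_method: str = "trapezoid",
) -> pd.DataFrame:
    """Per-participant endpoint frame for the adjusted analyses.

    Columns: ``pid, arm, age, gender, site, baseline, value, value_hib``
    where ``value_hib`` is the endpoint on the higher-is-better scale
    (PHQ-9 reduction from baseline, or the QALY itself). Participants with
    a missing baseline endpoint are dropped (relevant to imported data;
    the generator observes everyone at baseline).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    base = dataset.baseline().set_index("pid").sort_index()
    out = base[["arm", "age", "gender", "site"]].copy()
    if endpoint == "phq9":
        wide = dataset.pivot("phq9")
        post_week = dataset.design.occasions[1]
        out["baseline"] = wide[0]
        out["value"] = wide[post_week]
        out["value_hib"] = out["baseline"] - out["value"]
    else:
        util = utility_trajectories(dataset, utility_map)
        weeks = [float(w) for w in dataset.design.occasions]
        out["baseline"] = util[weeks[0]]
        out["value"] = qaly_12m(util[weeks].to_numpy(), weeks, method=qaly_method)
        out["value_hib"] = out["value"]
    out = out.dropna(subset=["baseline", "value"])
    return out.reset_index()


@dataclass(frozen=True)
class AdjustedEffect:
    """Arm coefficient of a covariate-adjusted linear endpoint model."""

    endpoint: str
    B: float
    ci_low: float
    ci_high: float
    p_value: float
    scale: str  # "native" or "reduction"
    covariates: tuple[str, ...] = ("age", "gender", "site", "baseline")
    n: int = 0

    def as_reduction(self) -> "AdjustedEffect":
        """Sign-flip a native PHQ-9 effect so positive = improvement."""
        if self.scale == "reduction":
            return self
        return replace(
            self,
            B=-self.B,
            ci_low=-self.ci_high,
            ci_high=-self.ci_low,
            scale="reduction",
        )


def adjusted_effect(
    dataset: TrialDataset,
    endpoint: str,
    utility_map: UtilityMap | None = None,
    robust: bool = True,
) -> AdjustedEffect:
    """Adjusted between-arm effect on an endpoint.

    OLS of the endpoint on an intervention indicator plus age, gender, study
    site (fixed categorical effects) and the baseline endpoint value, with
    HC3 heteroscedasticity-robust standard errors by default. For PHQ-9 the
    native-scale coefficient is returned (negative = fewer symptoms); use
    :meth:`AdjustedEffect.as_reduction` for the higher-is-better scale.
    """
    tab = endpoint_table(dataset, endpoint, utility_map)
    if tab.groupby("arm").size().reindex(["intervention", "control"]).fillna(0).min() < 2:
        raise ValueError("need at least 2 participants per arm")
    tab = tab.assign(
        arm_ind=(tab["arm"] == "intervention").astype(float),
        male=(tab["gender"] == "male").astype(float),
    )
    formula = "value ~ arm_ind + age + male + C(site) + baseline"
    model = smf.ols(formula, data=tab)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise SingularModelError(
            "singular adjustment design (collinear covariates or a site "
            "without variation); respecify rather than silently dropping terms"
        )
    fit = model.fit(cov_type="HC3" if robust else "nonrobust")
    ci = fit.conf_int().loc["arm_ind"]
    return AdjustedEffect(
        endpoint=endpoint,
        B=float(fit.params["arm_ind"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["arm_ind"]),
        scale="native",
        n=int(fit.nobs),
    )
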