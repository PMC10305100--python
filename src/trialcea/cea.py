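"""Bootstrapped ICERs, net-monetary-benefit regression and CEACs.

The incremental cost-effectiveness ratio (ICER) is the adjusted incremental
cost per unit of incremental effect, dC/dE, with effects on a
higher-is-better scale (PHQ-9 reductions, or QALYs). Its sampling
distribution is taken from a non-parametric bootstrap: participants are
resampled with replacement within each arm (arm sizes preserved), and the
covariate-adjusted dC and dE are re-estimated in every replicate. The
replicate cloud is summarised on the cost-effectiveness plane (x =
incremental effect, y = incremental cost; the south-east quadrant — more
effect at lower cost — is dominance).

The net monetary benefit (NMB) of a participant at willingness-to-pay
``lam`` is ``lam * effect - cost``; regressing it on the arm indicator plus
covariates gives the incremental NMB (INMB), linear in ``lam`` with slope
equal to the adjusted dE and intercept equal to minus the adjusted dC — so
the INMB line crosses zero exactly at the adjusted ICER. The
cost-effectiveness acceptability curve (CEAC) is the probability that the
INMB is positive as a function of ``lam``.

One covariate set (age, gender, site, baseline cost, baseline endpoint) is
used for the cost regression, the effect regression and the NMB regression,
which makes the x-intercept identity exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .costing import CostPanel
from .outcomes import SingularModelError, UtilityMap, endpoint_table
from .simulate import TrialDataset

__all__ = [
    "ICERResult",
    "NMBRegressionResult",
    "CEACCurve",
    "bootstrap_icer",
    "nmb_regression",
    "ceac",
    "ce_plane_export",
    "nmb_line_root",
    "analysis_frame",
    "DEFAULT_LAMBDA_GRIDS",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("NE", "SE", "SW", "NW")

#: Default willingness-to-pay grids (euros per effect unit). The PHQ-9 grid
#: spans 0-2000 euros per point of reduction; the QALY grid spans 0-100 000
#: euros per QALY, covering conventional decision thresholds.
DEFAULT_LAMBDA_GRIDS = {
    "phq9": np.arange(0.0, 2001.0, 10.0),
    "qaly": np.arange(0.0, 100001.0, 250.0),
}

#: Replicates with |dE| below this are excluded from ICER moments (their
#: ratio is numerically meaningless) but still count toward quadrants.
DEGENERATE_DE_TOL = 1e-10


def analysis_frame(
    dataset: TrialDataset,
    cost_panel: CostPanel,
    endpoint: str,
    scenario: str,
    utility_map: UtilityMap | None = None,
) -> pd.DataFrame:
    """Merge endpoint and cost data into one per-participant frame.

    Columns: ``pid, arm, arm_ind, age, male, site, baseline, value_hib,
    cost, baseline_cost``. Effects are on the higher-is-better scale.
    """
    eff = endpoint_table(dataset, endpoint, utility_map).set_index("pid")
    cp = cost_panel.data.set_index("pid")
    total_col = cost_panel.total_column(scenario)
    eff["cost"] = cp[total_col]
    eff["baseline_cost"] = cp["baseline_cost_annual"]
    eff = eff.dropna(subset=["cost", "baseline_cost"]).reset_index()
    eff["arm_ind"] = (eff["arm"] == "intervention").astype(float)
    eff["male"] = (eff["gender"] == "male").astype(float)
    return eff


def _design_matrix(frame: pd.DataFrame) -> np.ndarray:
    """[intercept, arm, age, male, site dummies (drop first), baseline cost,
    baseline endpoint]; the arm coefficient is column 1."""
    site_dummies = pd.get_dummies(frame["site"], drop_first=True, dtype=float)
    cols = [
        np.ones(len(frame)),
        frame["arm_ind"].to_numpy(),
        frame["age"].to_numpy(dtype=float),
        frame["male"].to_numpy(),
    ]
    cols.extend(site_dummies[c].to_numpy() for c in site_dummies.columns)
    cols.append(frame["baseline_cost"].to_numpy(dtype=float))
    cols.append(frame["baseline"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _fit_two(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS coefficients for two responses at once; minimum-norm on singular
    designs (e.g. a site level absent from a bootstrap replicate)."""
    try:
        return np.linalg.solve(X.T @ X, X.T @ Y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, Y, rcond=None)[0]


@dataclass
class ICERResult:
    """Bootstrap distribution of the adjusted ICER and its plane summary."""

    endpoint: str
    scenario: str
    n_reps: int
    seed: int
    mean_icer: float
    ci_low: float
    ci_high: float
    quadrant_shares: dict[str, float]
    delta_costs: np.ndarray = field(repr=False)
    delta_effects: np.ndarray = field(repr=False)
    n_degenerate: int = 0
    delta_cost_adj: float = float("nan")
    delta_effect_adj: float = float("nan")
    adjusted_icer: float = float("nan")
    mean_delta_cost: float = float("nan")
    mean_delta_effect: float = float("nan")

    def to_dict(self) -> dict:
        """JSON-ready summary (without the replicate cloud)."""
        return {
            "endpoint": self.endpoint,
            "scenario": self.scenario,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "mean_icer": self.mean_icer,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "quadrant_shares": self.quadrant_shares,
            "n_degenerate": self.n_degenerate,
            "delta_cost_adj": self.delta_cost_adj,
            "delta_effect_adj": self.delta_effect_adj,
            "adjusted_icer": self.adjusted_icer,
            "mean_delta_cost": self.mean_delta_cost,
            "mean_delta_effect": self.mean_delta_effect,
        }


def _quadrant_shares(de: np.ndarray, dc: np.ndarray) -> dict[str, float]:
    # Boundary convention: dC <= 0 counts as south, dE <= 0 as west.
    n = de.size
    if n == 0:
        return {q: float("nan") for q in QUADRANTS}
    ne = np.sum((de > 0) & (dc > 0))
    se = np.sum((de > 0) & (dc <= 0))
    sw = np.sum((de <= 0) & (dc <= 0))
    nw = np.sum((de <= 0) & (dc > 0))
    return {"NE": ne / n, "SE": se / n, "SW": sw / n, "NW": nw / n}


def bootstrap_icer(
    dataset: TrialDataset,
    cost_panel: CostPanel,
    endpoint: str,
    scenario: str,
    n_reps: int = 10_000,
    seed: int = 0,
    utility_map: UtilityMap | None = None,
) -> ICERResult:
    """Non-parametric bootstrap of the covariate-adjusted ICER.

    Resampling protocol (reproducible under a fixed seed): one
    ``numpy.random.default_rng(seed)`` generator; for each replicate the
    intervention-arm indices are drawn first, then the control-arm indices,
    each uniformly with replacement preserving the arm size; the adjusted
    dC and dE are then re-estimated by OLS on the replicate.

    Replicates with |dE| below machine tolerance are excluded from the mean
    and percentile ICER (with a logged count) but contribute to the
    quadrant shares.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    frame = analysis_frame(dataset, cost_panel, endpoint, scenario, utility_map)
    X = _design_matrix(frame)
    Y = np.column_stack(
        [frame["cost"].to_numpy(dtype=float), frame["value_hib"].to_numpy(dtype=float)]
    )
    int_rows = np.flatnonzero(frame["arm_ind"].to_numpy() == 1.0)
    ctl_rows = np.flatnonzero(frame["arm_ind"].to_numpy() == 0.0)
    n_int, n_ctl = int_rows.size, ctl_rows.size
    if min(n_int, n_ctl) < 2:
        raise ValueError("need at least 2 participants per arm")

    beta_full = _fit_two(X, Y)
    dc_adj, de_adj = float(beta_full[1, 0]), float(beta_full[1, 1])

    rng = np.random.default_rng(seed)
    dc = np.empty(n_reps)
    de = np.empty(n_reps)
    for r in range(n_reps):
        rows = np.concatenate(
            [
                int_rows[rng.integers(0, n_int, n_int)],
                ctl_rows[rng.integers(0, n_ctl, n_ctl)],
            ]
        )
        beta = _fit_two(X[rows], Y[rows])
        dc[r] = beta[1, 0]
        de[r] = beta[1, 1]

    valid = np.abs(de) > DEGENERATE_DE_TOL
    n_degenerate = int(n_reps - valid.sum())
    if n_degenerate:
        logger.info(
            "bootstrap_icer: excluded %d/%d replicates with |dE| <= %g from ICER moments",
            n_degenerate,
            n_reps,
            DEGENERATE_DE_TOL,
        )
    if valid.any():
        icers = dc[valid] / de[valid]
        mean_icer = float(icers.mean())
        lo, hi = (float(v) for v in np.percentile(icers, [2.5, 97.5]))
    else:
        mean_icer = lo = hi = float("nan")
    return ICERResult(
        endpoint=endpoint,
        scenario=scenario,
        n_reps=n_reps,
        seed=seed,
        mean_icer=mean_icer,
        ci_low=lo,
        ci_high=hi,
        quadrant_shares=_quadrant_shares(de, dc),
        delta_costs=dc,
        delta_effects=de,
        n_degenerate=n_degenerate,
        delta_cost_adj=dc_adj,
        delta_effect_adj=de_adj,
        adjusted_icer=dc_adj / de_adj if abs(de_adj) > DEGENERATE_DE_TOL else float("nan"),
        mean_delta_cost=float(dc.mean()),
        mean_delta_effect=float(de.mean()),
    )


@dataclass(frozen=True)
class NMBRegressionResult:
    """Incremental net monetary benefit at one willingness-to-pay value."""

    endpoint: str
    scenario: str
    lam: float
    inmb: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    acceptance_probability: float
    n: int

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "scenario": self.scenario,
            "lam": self.lam,
            "inmb": self.inmb,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se": self.se,
            "p_value": self.p_value,
            "acceptance_probability": self.acceptance_probability,
            "n": self.n,
        }


def nmb_regression(
    dataset: TrialDataset,
    cost_panel: CostPanel,
    endpoint: str,
    scenario: str,
    lam: float,
    utility_map: UtilityMap | None = None,
) -> NMBRegressionResult:
    """Regress per-participant NMB = lam*effect - cost on arm + covariates.

    Returns the arm coefficient (the INMB), its 95% CI (t-based, classical
    standard errors) and the acceptance probability P(INMB > 0) from the
    coefficient's t sampling distribution. At ``lam=0`` the INMB equals
    minus the adjusted incremental cost.
    """
    if lam < 0:
        raise ValueError("willingness to pay must be >= 0")
    frame = analysis_frame(dataset, cost_panel, endpoint, scenario, utility_map)
    frame["nmb"] = lam * frame["value_hib"] - frame["cost"]
    model = smf.ols(
        "nmb ~ arm_ind + age + male + C(site) + baseline_cost + baseline", data=frame
    )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise SingularModelError("singular NMB regression design")
    fit = model.fit()
    b = float(fit.params["arm_ind"])
    se = float(fit.bse["arm_ind"])
    lo, hi = (float(v) for v in fit.conf_int().loc["arm_ind"])
    accept = float(scipy.stats.t.cdf(b / se, fit.df_resid)) if se > 0 else float(b > 0)
    return NMBRegressionResult(
        endpoint=endpoint,
        scenario=scenario,
        lam=float(lam),
        inmb=b,
        ci_low=lo,
        ci_high=hi,
        se=se,
        p_value=float(fit.pvalues["arm_ind"]),
        acceptance_probability=accept,
        n=int(fit.nobs),
    )


def _first_crossing(grid: np.ndarray, values: np.ndarray) -> float | None:
    """Smallest lam at which ``values`` reaches >= 0, linearly interpolating
    between grid points; None if it never does."""
    nonneg = np.flatnonzero(values >= 0)
    if nonneg.size == 0:
        return None
    i = int(nonneg[0])
    if i == 0:
        return float(grid[0])
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = values[i - 1], values[i]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


@dataclass
class CEACCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""

    endpoint: str
    scenario: str
    grid: np.ndarray
    results: list[NMBRegressionResult]
    threshold_confident: float | None  # smallest lam with CI low >= 0
    threshold_minimum: float | None  # smallest lam with CI high >= 0
    prob_at_zero: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lam": [r.lam for r in self.results],
                "inmb": [r.inmb for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "acceptance_probability": [r.acceptance_probability for r in self.results],
            }
        )

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "scenario": self.scenario,
            "threshold_confident": self.threshold_confident,
            "threshold_minimum": self.threshold_minimum,
            "prob_at_zero": self.prob_at_zero,
            "curve": [r.to_dict() for r in self.results],
        }


def ceac(
    dataset: TrialDataset,
    cost_panel: CostPanel,
    endpoint: str,
    scenario: str,
    lam_grid=None,
    utility_map: UtilityMap | None = None,
) -> CEACCurve:
    """Evaluate the NMB regression over a willingness-to-pay grid.

    ``threshold_confident`` is the WTP above which the lower 95% confidence
    limit of the INMB is non-negative (one can be ~97.5% confident the
    intervention is cost-effective); ``threshold_minimum`` uses the upper
    limit (the WTP below which one is confident it is NOT). Both are
    linearly interpolated between grid points.
    """
    if lam_grid is None:
        lam_grid = DEFAULT_LAMBDA_GRIDS[endpoint]
    grid = np.asarray(lam_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("lam grid must be non-empty and strictly increasing")
    results = [
        nmb_regression(dataset, cost_panel, endpoint, scenario, lam, utility_map)
        for lam in grid
    ]
    lows = np.array([r.ci_low for r in results])
    highs = np.array([r.ci_high for r in results])
    if grid[0] == 0.0:
        at_zero = results[0]
    else:
        at_zero = nmb_regression(dataset, cost_panel, endpoint, scenario, 0.0, utility_map)
    return CEACCurve(
        endpoint=endpoint,
        scenario=scenario,
        grid=grid,
        results=results,
        threshold_confident=_first_crossing(grid, lows),
        threshold_minimum=_first_crossing(grid, highs),
        prob_at_zero=at_zero.acceptance_probability,
    )


def nmb_line_root(intercept: float, slope: float) -> float:
    """x-intercept of the INMB-vs-WTP line: the adjusted ICER.

    The INMB line is ``INMB(lam) = intercept + slope*lam`` with intercept
    -dC_adj and slope dE_adj, so its root -intercept/slope equals
    dC_adj/dE_adj.
    """
    if slope == 0:
        raise ZeroDivisionError("INMB line has zero slope; no finite root")
    return -intercept / slope


def ce_plane_export(icer_result: ICERResult) -> pd.DataFrame:
    """Replicate cloud as a plotting table: (delta_effect, delta_cost,
    quadrant), with quadrant shares in ``DataFrame.attrs['quadrant_shares']``."""
    de = icer_result.delta_effects
    dc = icer_result.delta_costs
    if de.size == 0:
        raise ValueError("empty replicate cloud")
    quadrant = np.where(
        de > 0, np.where(dc > 0, "NE", "SE"), np.where(dc > 0, "NW", "SW")
    )
    table = pd.DataFrame(
        {"delta_effect": de, "delta_cost": dc, "quadrant": quadrant}
    )
    table.attrs["quadrant_shares"] = dict(icer_result.quadrant_shares)
    return table
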