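"""Fitted-model interface: CostEffectivenessModel -> CEAResults.

The model binds one trial dataset to a costing configuration, an endpoint
and a scenario; ``fit`` runs LOCF imputation, costing, the adjusted effect
and cost-ratio models and the ICER bootstrap, returning a results object
that carries the estimates and exposes NMB regressions, CEACs and plotting.

Example
-------
>>> from trialcea import TrialDesign, SimParams, simulate_trial
>>> from trialcea import CostEffectivenessModel
>>> data = simulate_trial(TrialDesign(), SimParams(seed=1))
>>> res = CostEffectivenessModel(data, endpoint="phq9", scenario="base").fit(
...     n_reps=2000, seed=1
... )
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea, costing, econometrics, outcomes
from .costing import CostPanel, ProgrammeCostLedger, UnitCostTable
from .outcomes import AdjustedEffect, UtilityMap
from .simulate import TrialDataset

__all__ = ["CostEffectivenessModel", "CEAResults"]


class CostEffectivenessModel:
    """Trial-based cost-effectiveness (or cost-utility) model.

    Parameters
    ----------
    dataset
        A :class:`~trialcea.simulate.TrialDataset` (simulated or imported).
    unit_costs, programme_ledger
        Costing configuration; the bundled illustrative defaults are used
        when omitted.
    endpoint
        ``"phq9"`` (cost-effectiveness per point of PHQ-9 reduction) or
        ``"qaly"`` (cost-utility per QALY).
    scenario
        ``"base"``, ``"on_top"`` or ``"optimal"``.
    utility_map
        Optional domain-to-utility mapping overriding the equal-weight
        default.
    annualization
        Resource-use annualization rule (see
        :func:`~trialcea.costing.annualize_resource_use`).
    """

    def __init__(
        self,
        dataset: TrialDataset,
        unit_costs: UnitCostTable | None = None,
        programme_ledger: ProgrammeCostLedger | None = None,
        endpoint: str = "phq9",
        scenario: str = "base",
        utility_map: UtilityMap | None = None,
        annualization: str = "scale_52",
        qaly_method: str = "trapezoid",
    ) -> None:
        if endpoint not in outcomes.ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        if scenario not in costing.SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        self.dataset = dataset
        self.unit_costs = unit_costs or costing.default_unit_cost_table()
        self.programme_ledger = programme_ledger or costing.default_programme_ledger()
        self.endpoint = endpoint
        self.scenario = scenario
        self.utility_map = utility_map
        self.annualization = annualization
        self.qaly_method = qaly_method

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, design=None, **kwargs) -> "CostEffectivenessModel":
        """Build from a tidy long-format DataFrame (see TrialDataset)."""
        from .simulate import TrialDesign

        if design is None:
            weeks = tuple(int(w) for w in sorted(data["week"].unique()))
            arms = data[data["week"] == 0]["arm"].value_counts()
            design = TrialDesign(
                n_intervention=int(arms.get("intervention", 0)),
                n_control=int(arms.get("control", 0)),
                n_sites=int(data["site"].nunique()),
                occasions=weeks,
            )
        return cls(TrialDataset(data=data, design=design), **kwargs)

    def fit(self, n_reps: int = 10_000, seed: int = 0) -> "CEAResults":
        """Run the full estimation chain and return a results object."""
        complete = outcomes.locf_impute(self.dataset)
        panel = costing.annualize_resource_use(
            complete, self.unit_costs, method=self.annualization
        )
        costing.build_all_scenarios(panel, self.programme_ledger)
        effect = outcomes.adjusted_effect(complete, self.endpoint, self.utility_map)
        try:
            cost_ratio = econometrics.fit_cost_glm(panel, component="resource_use")
        except econometrics.DegenerateDataError:
            cost_ratio = None
        icer = cea.bootstrap_icer(
            complete,
            panel,
            self.endpoint,
            self.scenario,
            n_reps=n_reps,
            seed=seed,
            utility_map=self.utility_map,
        )
        nmb0 = cea.nmb_regression(
            complete, panel, self.endpoint, self.scenario, 0.0, self.utility_map
        )
        return CEAResults(
            model=self,
            complete_dataset=complete,
            cost_panel=panel,
            effect=effect,
            cost_ratio=cost_ratio,
            icer=icer,
            nmb_at_zero=nmb0,
            n_reps=n_reps,
            seed=seed,
        )


@dataclass
class CEAResults:
    """Estimates, uncertainty and diagnostics from a fitted model."""

    model: CostEffectivenessModel
    complete_dataset: TrialDataset
    cost_panel: CostPanel
    effect: AdjustedEffect
    cost_ratio: econometrics.CostRatioResult | None
    icer: cea.ICERResult
    nmb_at_zero: cea.NMBRegressionResult
    n_reps: int
    seed: int
    _ceac_cache: dict = field(default_factory=dict, repr=False)

    @property
    def endpoint(self) -> str:
        return self.model.endpoint

    @property
    def scenario(self) -> str:
        return self.model.scenario

    def nmb(self, lam: float) -> cea.NMBRegressionResult:
        """Incremental NMB regression at one willingness-to-pay value."""
        return cea.nmb_regression(
            self.complete_dataset,
            self.cost_panel,
            self.endpoint,
            self.scenario,
            lam,
            self.model.utility_map,
        )

    def ceac(self, lam_grid=None) -> cea.CEACCurve:
        """CEAC over a willingness-to-pay grid (cached per grid)."""
        key = None if lam_grid is None else tuple(np.asarray(lam_grid, dtype=float))
        if key not in self._ceac_cache:
            self._ceac_cache[key] = cea.ceac(
                self.complete_dataset,
                self.cost_panel,
                self.endpoint,
                self.scenario,
                lam_grid,
                self.model.utility_map,
            )
        return self._ceac_cache[key]

    def ce_plane_table(self) -> pd.DataFrame:
        return cea.ce_plane_export(self.icer)

    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        eff = self.effect
        eff_red = eff.as_reduction() if self.endpoint == "phq9" else eff
        unit = "PHQ-9 point reduction" if self.endpoint == "phq9" else "QALY"
        lines = [
            "Trial-based cost-effectiveness analysis",
            "=" * 55,
            f"Endpoint:           {self.endpoint} (effect unit: {unit})",
            f"Scenario:           {self.scenario}",
            f"Participants:       {eff.n}",
            f"Bootstrap reps:     {self.n_reps} (seed {self.seed}, "
            f"{self.icer.n_degenerate} degenerate)",
            "-" * 55,
            f"Adjusted effect B:  {eff.B:.3f}  "
            f"(95% CI {eff.ci_low:.3f} to {eff.ci_high:.3f}, p={eff.p_value:.3g})",
        ]
        if self.cost_ratio is not None:
            cr = self.cost_ratio
            lines.append(
                f"Cost ratio Exp(B):  {cr.exp_b:.2f}  "
                f"(95% CI {cr.ci_low:.2f} to {cr.ci_high:.2f}, p={cr.p_value:.3g})"
            )
        q = self.icer.quadrant_shares
        lines += [
            f"Adjusted dC:        {self.icer.delta_cost_adj:.1f} EUR",
            f"Adjusted dE:        {eff_red.B:.3f} {unit}s",
            f"Adjusted ICER:      {self.icer.adjusted_icer:.1f} EUR per {unit}",
            f"Bootstrap ICER:     {self.icer.mean_icer:.1f} "
            f"(95% CI {self.icer.ci_low:.1f} to {self.icer.ci_high:.1f})",
            "Quadrant shares:    "
            + ", ".join(f"{k} {q[k] * 100:.1f}%" for k in ("NE", "SE", "SW", "NW")),
            f"INMB at WTP=0:      {self.nmb_at_zero.inmb:.1f} EUR "
            f"(95% CI {self.nmb_at_zero.ci_low:.1f} to {self.nmb_at_zero.ci_high:.1f})",
            f"P(cost-effective | WTP=0): {self.nmb_at_zero.acceptance_probability:.3f}",
        ]
        return "\n".join(lines)

    # -- plotting (thin wrappers; tables are the primary interface) --------

    def plot_ce_plane(self, ax=None):
        """Scatter the bootstrap replicate cloud on the CE plane."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.ce_plane_table()
        ax.scatter(tab["delta_effect"], tab["delta_cost"], s=4, alpha=0.3)
        ax.axhline(0, color="grey", lw=0.8)
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel("Incremental effect")
        ax.set_ylabel("Incremental cost (EUR)")
        return ax

    def plot_nmb_line(self, lam_grid=None, ax=None):
        """INMB (with 95% CI band) against willingness to pay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac(lam_grid).to_frame()
        ax.plot(curve["lam"], curve["inmb"], label="INMB")
        ax.fill_between(curve["lam"], curve["ci_low"], curve["ci_high"], alpha=0.2)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel("Willingness to pay (EUR)")
        ax.set_ylabel("Incremental net monetary benefit (EUR)")
        return ax

    def plot_ceac(self, lam_grid=None, ax=None):
        """Acceptance probability against willingness to pay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac(lam_grid).to_frame()
        ax.plot(curve["lam"], curve["acceptance_probability"])
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (EUR)")
        ax.set_ylabel("P(cost-effective)")
        return ax
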