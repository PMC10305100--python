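"""Synthetic two-arm trial generator with analytic ground truth.

Emulates the data structure of a two-arm randomised trial in moderately
depressed adults: four measurement occasions (baseline, post-intervention
at 12 weeks, follow-ups at 24 and 48 weeks), PHQ-9 depression scores, the
26-item WHOQOL-BREF quality-of-life instrument, and per-category health
service contacts recalled over a 13-week window. Costs are right-skewed
(Bernoulli-gated gamma draws, so exact-zero windows occur), sites differ
by a multiplicative cost factor, and missingness is monotone dropout, so
last-observation-carried-forward imputation is well defined.

``ground_truth`` returns the analytic expectations implied by the
parameters (complete-data, i.e. no-dropout, expectations) for
parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .costing import SERVICE_CATEGORIES, UnitCostTable, default_unit_cost_table

__all__ = [
    "TrialDesign",
    "SimParams",
    "TrialDataset",
    "GroundTruth",
    "ParameterError",
    "simulate_trial",
    "ground_truth",
    "write_dataset",
    "read_dataset",
    "default_cost_scales",
]

ARMS = ("intervention", "control")

#: WHOQOL-BREF items whose raw response is reverse-scored (1-indexed).
REVERSE_ITEMS = (3, 4, 26)


class ParameterError(ValueError):
    """Invalid trial design or simulation parameters."""


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm trial layout: arm sizes, sites and measurement schedule."""

    n_intervention: int = 81
    n_control: int = 68
    n_sites: int = 7
    occasions: tuple[int, ...] = (0, 12, 24, 48)  # week offsets from baseline
    recall_window_weeks: int = 13

    def __post_init__(self) -> None:
        if self.n_intervention < 2 or self.n_control < 2:
            raise ParameterError("each arm needs at least 2 participants")
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        occ = tuple(self.occasions)
        if len(occ) < 2 or occ[0] != 0 or any(b <= a for a, b in zip(occ, occ[1:])):
            raise ParameterError("occasions must be strictly increasing and start at 0")
        if self.recall_window_weeks < 1:
            raise ParameterError("recall_window_weeks must be >= 1")
        object.__setattr__(self, "occasions", occ)

    @property
    def n_total(self) -> int:
        return self.n_intervention + self.n_control

    @property
    def occasion_labels(self) -> tuple[str, ...]:
        return tuple(f"T{i}" for i in range(len(self.occasions)))


# Expected per-recall-window cost (euros) per category and arm, at the
# default unit costs. Chosen so that the annualized resource-use means are
# ~1401 euros/year (intervention) and ~2232 euros/year (control), with the
# mental-health share ~15% vs ~40% of the total.
_DEFAULT_OCCASION_COST = {
    "gp": {"intervention": 45.0, "control": 45.0},
    "outpatient_specialist": {"intervention": 38.0, "control": 40.0},
    "emergency": {"intervention": 25.0, "control": 30.0},
    "mental_health_specialist": {"intervention": 52.54, "control": 223.18},
    "therapist": {"intervention": 25.0, "control": 25.0},
    "counselling": {"intervention": 25.0, "control": 20.0},
    "pharmacy": {"intervention": 14.735, "control": 14.77},
    "inpatient_general": {"intervention": 55.0, "control": 60.0},
    "inpatient_psychiatric": {"intervention": 70.0, "control": 100.0},
}


def default_cost_scales(
    cost_shape: float = 0.8,
    use_probability: float = 0.5,
    unit_costs: Mapping[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Gamma scales giving the default expected per-window category costs.

    The expected per-window cost of a category is
    ``use_probability * shape * scale * unit_cost``; this inverts that
    identity for the default cost mix.
    """
    if unit_costs is None:
        unit_costs = default_unit_cost_table().unit_costs
    scales: dict[str, dict[str, float]] = {}
    for cat in SERVICE_CATEGORIES:
        scales[cat] = {
            arm: _DEFAULT_OCCASION_COST[cat][arm]
            / (use_probability * cost_shape * unit_costs[cat])
            for arm in ARMS
        }
    return scales


@dataclass
class SimParams:
    """Generator parameters; defaults are the package's study conditions.

    Treatment effects are additive shifts applied to the intervention arm
    from the post-intervention occasion onwards: ``phq_treatment_effect``
    in PHQ-9 points (negative = fewer symptoms), ``utility_treatment_effect``
    on the 0-1 utility scale. Costs per category and window are
    ``Bernoulli(use_probability) * Gamma(cost_shape, scale)`` contact
    intensities multiplied by unit costs; ``cost_scale_by_category_and_arm``
    maps category -> arm -> gamma scale.
    """

    cost_shape: float = 0.8
    use_probability: float = 0.5
    cost_scale_by_category_and_arm: dict[str, dict[str, float]] = field(
        default_factory=default_cost_scales
    )
    site_cost_multipliers: tuple[float, ...] = (0.70, 0.80, 0.90, 1.00, 1.10, 1.20, 1.30)
    baseline_phq_mean: float = 17.0
    baseline_phq_sd: float = 1.4
    phq_treatment_effect: float = -2.0
    phq_control_drift: float = 0.7
    phq_noise_sd: float = 4.0
    baseline_utility_mean: float = 0.45
    baseline_utility_sd: float = 0.12
    utility_treatment_effect: float = 0.04
    utility_noise_sd: float = 0.08
    item_noise_sd: float = 0.55
    prop_male: float = 0.617
    age_mean: float = 32.2
    age_sd: float = 9.4
    dropout_prob_per_occasion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("use_probability", "dropout_prob_per_occasion", "prop_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.cost_shape <= 0:
            raise ParameterError("cost_shape must be > 0")
        for cat, by_arm in self.cost_scale_by_category_and_arm.items():
            for arm, s in by_arm.items():
                if s <= 0:
                    raise ParameterError(f"gamma scale for {cat}/{arm} must be > 0")
        if any(m <= 0 for m in self.site_cost_multipliers):
            raise ParameterError("site cost multipliers must be > 0")
        if not 15.0 <= self.baseline_phq_mean <= 19.0:
            raise ParameterError("baseline_phq_mean must lie in the inclusion window [15, 19]")
        for name in ("phq_noise_sd", "baseline_phq_sd", "utility_noise_sd",
                     "baseline_utility_sd", "item_noise_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class TrialDataset:
    """A simulated or imported trial in tidy long format.

    ``data`` has one row per participant-occasion: ``pid, arm, age, gender,
    site, occasion, week, observed``, ``phq9``, ``item_01..item_26``
    (WHOQOL-BREF raw responses) and ``ru_<category>`` resource-use counts.
    Unobserved occasions carry NaN outcome/resource values.
    """

    data: pd.DataFrame
    design: TrialDesign
    params: SimParams | None = None

    @property
    def item_columns(self) -> list[str]:
        return [f"item_{i:02d}" for i in range(1, 27)]

    @property
    def ru_columns(self) -> list[str]:
        return [f"ru_{c}" for c in SERVICE_CATEGORIES]

    @property
    def value_columns(self) -> list[str]:
        return ["phq9"] + self.item_columns + self.ru_columns

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["week"] == 0]

    def pivot(self, column: str) -> pd.DataFrame:
        """Participant x occasion wide table of one value column."""
        return self.data.pivot(index="pid", columns="week", values=column)


@dataclass(frozen=True)
class GroundTruth:
    """Complete-data expectations implied by the generator parameters."""

    true_delta_cost: float  # annual resource-use euros, intervention - control
    true_delta_phq: float  # PHQ-9 points at post-intervention (negative = better)
    true_delta_phq_reduction: float  # on the higher-is-better reduction scale
    true_delta_utility: float  # utility points from post-intervention onwards
    true_delta_qaly: float  # 12-month QALY difference
    mean_annual_cost_by_arm: dict[str, float]
    mean_baseline_annual_cost_by_arm: dict[str, float]
    mean_qaly_by_arm: dict[str, float]


def _qaly_weight(occasions: tuple[int, ...], horizon: float = 52.0) -> float:
    """12-month QALY gain from a unit utility shift at every post-baseline occasion."""
    weeks = np.asarray(occasions, dtype=float)
    u = np.ones_like(weeks)
    u[0] = 0.0
    area = np.trapezoid(u, weeks) + u[-1] * (horizon - weeks[-1])
    return float(area / horizon)


def ground_truth(
    design: TrialDesign,
    params: SimParams,
    unit_costs: Mapping[str, float] | None = None,
) -> GroundTruth:
    """Analytic expectations for parameter-recovery tests (no simulation).

    Costs use the gamma mean identity: the expected per-window cost of a
    category is ``use_prob * shape * scale * unit_cost`` times the average
    site multiplier, and the annualization factor is ``52/recall_window``.
    Expectations are for complete data; dropout plus LOCF attenuates arm
    effects relative to these values.
    """
    if unit_costs is None:
        unit_costs = default_unit_cost_table().unit_costs
    mult = float(np.mean(params.site_cost_multipliers[: design.n_sites]))
    annual_factor = 52.0 / design.recall_window_weeks
    annual = {}
    for arm in ARMS:
        occ_cost = sum(
            params.use_probability
            * params.cost_shape
            * params.cost_scale_by_category_and_arm[cat][arm]
            * unit_costs[cat]
            for cat in SERVICE_CATEGORIES
        )
        annual[arm] = occ_cost * mult * annual_factor
    w = _qaly_weight(design.occasions)
    u0 = params.baseline_utility_mean
    mean_qaly = {
        "control": u0,
        "intervention": u0 + w * params.utility_treatment_effect,
    }
    return GroundTruth(
        true_delta_cost=annual["intervention"] - annual["control"],
        true_delta_phq=params.phq_treatment_effect,
        true_delta_phq_reduction=-params.phq_treatment_effect,
        true_delta_utility=params.utility_treatment_effect,
        true_delta_qaly=w * params.utility_treatment_effect,
        mean_annual_cost_by_arm=annual,
        mean_baseline_annual_cost_by_arm=dict(annual),
        mean_qaly_by_arm=mean_qaly,
    )


def simulate_trial(design: TrialDesign, params: SimParams) -> TrialDataset:
    """Draw one trial. Identical (design, params.seed) gives identical data.

    Random draws happen in a fixed order (demographics, PHQ-9, utilities,
    items, resource use, dropout), each as a single vectorised call, so the
    output is bit-reproducible for a given seed.
    """
    if len(params.site_cost_multipliers) < design.n_sites:
        raise ParameterError(
            f"need >= {design.n_sites} site cost multipliers, "
            f"got {len(params.site_cost_multipliers)}"
        )
    rng = np.random.default_rng(params.seed)
    n = design.n_total
    n_occ = len(design.occasions)
    n_cat = len(SERVICE_CATEGORIES)
    arm = np.array(["intervention"] * design.n_intervention + ["control"] * design.n_control)
    is_int = arm == "intervention"

    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 65.0)
    male = rng.random(n) < params.prop_male
    site_idx = rng.integers(0, design.n_sites, n)

    # PHQ-9: baseline inside the inclusion window [15, 19]; follow-ups drift
    # plus the arm effect from post-intervention onwards.
    phq0 = np.round(
        np.clip(rng.normal(params.baseline_phq_mean, params.baseline_phq_sd, n), 15, 19)
    )
    phq_noise = rng.normal(0.0, params.phq_noise_sd, (n, n_occ - 1))
    phq = np.empty((n, n_occ))
    phq[:, 0] = phq0
    shift = params.phq_control_drift + np.where(is_int, params.phq_treatment_effect, 0.0)
    for t in range(1, n_occ):
        phq[:, t] = np.clip(np.round(phq0 + shift + phq_noise[:, t - 1]), 0, 27)

    # Latent quality-of-life level in [0, 1]; measured through the 26 items.
    q0 = np.clip(
        rng.normal(params.baseline_utility_mean, params.baseline_utility_sd, n), 0.02, 0.98
    )
    u_noise = rng.normal(0.0, params.utility_noise_sd, (n, n_occ - 1))
    q = np.empty((n, n_occ))
    q[:, 0] = q0
    u_shift = np.where(is_int, params.utility_treatment_effect, 0.0)
    for t in range(1, n_occ):
        q[:, t] = np.clip(q0 + u_shift + u_noise[:, t - 1], 0.01, 0.99)

    item_noise = rng.normal(0.0, params.item_noise_sd, (n, n_occ, 26))
    scored = np.clip(np.round(1.0 + 4.0 * q[:, :, None] + item_noise), 1, 5)
    items = scored.copy()
    for i in REVERSE_ITEMS:  # store raw responses; scoring reverses them back
        items[:, :, i - 1] = 6 - scored[:, :, i - 1]

    scale = np.empty((n, n_cat))
    for j, cat in enumerate(SERVICE_CATEGORIES):
        by_arm = params.cost_scale_by_category_and_arm[cat]
        scale[:, j] = np.where(is_int, by_arm["intervention"], by_arm["control"])
    scale *= np.asarray(params.site_cost_multipliers)[site_idx][:, None]
    gamma = rng.gamma(params.cost_shape, 1.0, (n, n_occ, n_cat))
    gate = rng.random((n, n_occ, n_cat)) < params.use_probability
    counts = gamma * gate * scale[:, None, :]

    # Monotone dropout: everyone observed at baseline; once gone, gone.
    observed = np.ones((n, n_occ), dtype=bool)
    drop_u = rng.random((n, n_occ - 1))
    for t in range(1, n_occ):
        observed[:, t] = observed[:, t - 1] & (drop_u[:, t - 1] >= params.dropout_prob_per_occasion)

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    blocks = []
    for t, week in enumerate(design.occasions):
        obs_t = observed[:, t]
        block = pd.DataFrame(
            {
                "pid": pid,
                "arm": arm,
                "age": age,
                "gender": np.where(male, "male", "female"),
                "site": np.array([f"S{s + 1}" for s in site_idx]),
                "occasion": f"T{t}",
                "week": week,
                "observed": obs_t,
                "phq9": np.where(obs_t, phq[:, t], np.nan),
            }
        )
        for i in range(26):
            block[f"item_{i + 1:02d}"] = np.where(obs_t, items[:, t, i], np.nan)
        for j, cat in enumerate(SERVICE_CATEGORIES):
            block[f"ru_{cat}"] = np.where(obs_t, counts[:, t, j], np.nan)
        blocks.append(block)
    data = (
        pd.concat(blocks, ignore_index=True)
        .sort_values(["pid", "week"], kind="stable")
        .reset_index(drop=True)
    )
    return TrialDataset(data=data, design=design, params=params)


def _params_to_jsonable(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_dataset(dataset: TrialDataset, csv_path, sidecar_path=None) -> None:
    """Write the tidy table as CSV plus a JSON sidecar of design, parameters
    and ground truth."""
    dataset.data.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        payload = {"design": _params_to_jsonable(dataset.design)}
        if dataset.params is not None:
            payload["params"] = _params_to_jsonable(dataset.params)
            payload["ground_truth"] = dataclasses.asdict(
                ground_truth(dataset.design, dataset.params)
            )
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def read_dataset(csv_path, sidecar_path=None) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset` (or compatible)."""
    data = pd.read_csv(csv_path)
    design = None
    params = None
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            payload = json.load(fh)
        d = payload["design"]
        d["occasions"] = tuple(d["occasions"])
        design = TrialDesign(**d)
        if "params" in payload:
            p = payload["params"]
            p["site_cost_multipliers"] = tuple(p["site_cost_multipliers"])
            params = SimParams(**p)
    if design is None:
        weeks = tuple(int(w) for w in sorted(data["week"].unique()))
        arms = data[data["week"] == 0]["arm"].value_counts()
        design = TrialDesign(
            n_intervention=int(arms.get("intervention", 0)),
            n_control=int(arms.get("control", 0)),
            n_sites=int(data["site"].nunique()),
            occasions=weeks,
        )
    return TrialDataset(data=data, design=design, params=params)
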