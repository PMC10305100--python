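"""Pipeline orchestration: run the full analysis and write every artifact.

``run_pipeline`` chains simulate-or-load -> LOCF -> costing/scenarios ->
endpoints -> cost GLMs -> bootstrap ICERs -> NMB/CEAC per endpoint x
scenario, writing delimited tables and JSON results plus a machine-readable
run manifest (library versions, seed, config hash) that suffices to
reproduce every number. ``table1_like`` builds the per-arm cost comparison
table (category means, s.d. and adjusted Exp(B) ratios).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cea, costing, econometrics, outcomes, simulate
from .costing import CostPanel, ProgrammeCostLedger, UnitCostTable

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "run_pipeline",
    "table1_like",
    "n_weighted_mean",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run.

    When ``dataset_csv`` is unset a trial is simulated from ``design`` and
    ``sim_params`` (the generator seed is overridden by ``seed``).
    """

    out_dir: str = "trialcea_out"
    dataset_csv: str | None = None
    dataset_sidecar: str | None = None
    unit_cost_yaml: str | None = None
    ledger_yaml: str | None = None
    scenarios: tuple[str, ...] = ("base", "on_top", "optimal")
    endpoints: tuple[str, ...] = ("phq9", "qaly")
    n_reps: int = 10_000
    seed: int = 0
    lam_grids: dict = field(default_factory=dict)  # endpoint -> [start, stop, step]
    design: dict = field(default_factory=dict)
    sim_params: dict = field(default_factory=dict)
    annualization: str = "scale_52"

    def __post_init__(self) -> None:
        if len(self.scenarios) == 0:
            raise ValueError("scenario list must not be empty")
        if len(self.endpoints) == 0:
            raise ValueError("endpoint list must not be empty")
        unknown = set(self.scenarios) - set(costing.SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        unknown = set(self.endpoints) - set(outcomes.ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for path_attr in ("dataset_csv", "dataset_sidecar", "unit_cost_yaml", "ledger_yaml"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr}: no such file {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("scenarios", "endpoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["endpoints"] = list(self.endpoints)
        return d


def n_weighted_mean(means, ns) -> float:
    """Pooled mean of group means weighted by group sizes."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float(np.sum(means * ns) / np.sum(ns))


def table1_like(
    cost_panel: CostPanel, scenario: str = "base", with_glm: bool = True
) -> pd.DataFrame:
    """Per-arm annual cost comparison by category, with adjusted ratios.

    One row per service category plus the resource-use total and the
    scenario total; columns are per-arm means and standard deviations, the
    size-weighted pooled mean, and (optionally) the gamma-GLM Exp(B) with
    confidence limits. Categories whose costs cannot support a gamma model
    (e.g. an all-zero arm) carry NaN in the GLM columns.
    """
    df = cost_panel.data
    total_col = cost_panel.total_column(scenario)
    rows = [(f"cost_{c}", c) for c in costing.SERVICE_CATEGORIES]
    rows += [("resource_cost_annual", "resource_use_total"), (total_col, f"total_{scenario}")]
    n_by_arm = df.groupby("arm").size()
    records = []
    for col, label in rows:
        rec = {"component": label}
        means = []
        for arm in ("intervention", "control"):
            sub = df.loc[df["arm"] == arm, col]
            rec[f"mean_{arm}"] = sub.mean()
            rec[f"sd_{arm}"] = sub.std(ddof=1)
            means.append(sub.mean())
        rec["pooled_mean"] = n_weighted_mean(
            means, [n_by_arm["intervention"], n_by_arm["control"]]
        )
        if with_glm:
            component = (
                "resource_use"
                if label == "resource_use_total"
                else ("total" if col == total_col else label)
            )
            try:
                glm = econometrics.fit_cost_glm(
                    cost_panel,
                    scenario=scenario if component == "total" else None,
                    component=component,
                )
                rec["exp_b"] = glm.exp_b
                rec["exp_b_ci_low"] = glm.ci_low
                rec["exp_b_ci_high"] = glm.ci_high
                rec["p_value"] = glm.p_value
            except (econometrics.DegenerateDataError, econometrics.ConvergenceError):
                rec["exp_b"] = rec["exp_b_ci_low"] = rec["exp_b_ci_high"] = np.nan
                rec["p_value"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _lam_grid(config: AnalysisConfig, endpoint: str):
    if endpoint in config.lam_grids:
        start, stop, step = config.lam_grids[endpoint]
        return np.arange(float(start), float(stop) + float(step) / 2, float(step))
    return cea.DEFAULT_LAMBDA_GRIDS[endpoint]


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the configured analysis end to end; returns the result bundle.

    Writes (under ``config.out_dir``): the dataset (CSV + JSON sidecar),
    the cost panel, per-endpoint tables, GLM cost ratios (JSON), per
    endpoint x scenario ICER results (JSON) with CE-plane tables (CSV),
    CEAC tables (CSV) and results (JSON), the Table-1-like cost comparison,
    and ``manifest.json``. Identical configs produce byte-identical numeric
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config, "artifacts": []}

    def emit(path: Path):
        bundle["artifacts"].append(str(path))

    with _stage("load_or_simulate"):
        if config.dataset_csv is not None:
            dataset = simulate.read_dataset(config.dataset_csv, config.dataset_sidecar)
        else:
            design = simulate.TrialDesign(**config.design)
            params_kw = dict(config.sim_params)
            params_kw["seed"] = config.seed
            dataset = simulate.simulate_trial(design, simulate.SimParams(**params_kw))
        simulate.write_dataset(dataset, out / "dataset.csv", out / "dataset.json")
        emit(out / "dataset.csv")

    with _stage("locf"):
        complete = outcomes.locf_impute(dataset)

    with _stage("costing"):
        table = (
            UnitCostTable.from_yaml(config.unit_cost_yaml)
            if config.unit_cost_yaml
            else costing.default_unit_cost_table()
        )
        ledger = (
            ProgrammeCostLedger.from_yaml(config.ledger_yaml)
            if config.ledger_yaml
            else costing.default_programme_ledger()
        )
        panel = costing.annualize_resource_use(complete, table, method=config.annualization)
        costing.build_all_scenarios(panel, ledger)
        panel.to_csv(out / "cost_panel.csv")
        emit(out / "cost_panel.csv")

    with _stage("endpoints"):
        endpoint_frames = {}
        for ep in config.endpoints:
            tab = outcomes.endpoint_table(complete, ep)
            tab.to_csv(out / f"endpoints_{ep}.csv", index=False)
            emit(out / f"endpoints_{ep}.csv")
            endpoint_frames[ep] = tab

    with _stage("cost_glm"):
        glm_records = []
        try:
            glm_records.append(
                dataclasses.asdict(econometrics.fit_cost_glm(panel, component="resource_use"))
            )
        except econometrics.DegenerateDataError as exc:
            glm_records.append({"component": "resource_use", "error": str(exc)})
        for sc in config.scenarios:
            try:
                glm_records.append(
                    dataclasses.asdict(
                        econometrics.fit_cost_glm(panel, scenario=sc, component="total")
                    )
                )
            except econometrics.DegenerateDataError as exc:
                glm_records.append({"component": "total", "scenario": sc, "error": str(exc)})
        with open(out / "glm_results.json", "w") as fh:
            json.dump(glm_records, fh, indent=2, sort_keys=True, default=list)
        emit(out / "glm_results.json")

    with _stage("table1"):
        table1_like(panel, scenario="base").to_csv(out / "table1.csv", index=False)
        emit(out / "table1.csv")

    with _stage("cea"):
        bundle["icer"] = {}
        bundle["ceac"] = {}
        for ep in config.endpoints:
            for sc in config.scenarios:
                icer = cea.bootstrap_icer(
                    complete, panel, ep, sc, n_reps=config.n_reps, seed=config.seed
                )
                bundle["icer"][(ep, sc)] = icer
                with open(out / f"icer_{ep}_{sc}.json", "w") as fh:
                    json.dump(icer.to_dict(), fh, indent=2, sort_keys=True)
                emit(out / f"icer_{ep}_{sc}.json")
                cea.ce_plane_export(icer).to_csv(out / f"ce_plane_{ep}_{sc}.csv", index=False)
                emit(out / f"ce_plane_{ep}_{sc}.csv")
                curve = cea.ceac(complete, panel, ep, sc, _lam_grid(config, ep))
                bundle["ceac"][(ep, sc)] = curve
                curve.to_frame().to_csv(out / f"ceac_{ep}_{sc}.csv", index=False)
                emit(out / f"ceac_{ep}_{sc}.csv")
                with open(out / f"ceac_{ep}_{sc}.json", "w") as fh:
                    json.dump(curve.to_dict(), fh, indent=2, sort_keys=True)
                emit(out / f"ceac_{ep}_{sc}.json")

    with _stage("manifest"):
        import statsmodels

        manifest = {
            "trialcea_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "statsmodels_version": statsmodels.__version__,
            "seed": config.seed,
            "n_reps": config.n_reps,
            "config": config.to_jsonable(),
            "config_sha256": _config_hash(config),
            "artifacts": sorted(bundle["artifacts"]),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle["dataset"] = dataset
    bundle["cost_panel"] = panel
    bundle["endpoint_frames"] = endpoint_frames
    return bundle
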