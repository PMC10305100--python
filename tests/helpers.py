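"""Shared test utilities: quick trial construction and pipeline shortcuts."""

from __future__ import annotations

import copy

import trialcea as t
from trialcea.simulate import default_cost_scales


def make_trial(
    n_int=30,
    n_ctl=30,
    n_sites=2,
    seed=7,
    dropout=0.1,
    occasions=(0, 12, 24, 48),
    **param_kw,
):
    design = t.TrialDesign(
        n_intervention=n_int, n_control=n_ctl, n_sites=n_sites, occasions=occasions
    )
    params = t.SimParams(seed=seed, dropout_prob_per_occasion=dropout, **param_kw)
    return t.simulate_trial(design, params)


def equal_arm_scales():
    """Cost scales with the control arm copied from the intervention arm."""
    scales = default_cost_scales()
    for cat in scales:
        scales[cat]["control"] = scales[cat]["intervention"]
    return scales


def scaled_control_scales(factor):
    """Control-arm gamma scales = intervention scales x factor."""
    scales = equal_arm_scales()
    for cat in scales:
        scales[cat]["control"] = scales[cat]["intervention"] * factor
    return copy.deepcopy(scales)


def null_params(seed, **kw):
    """No arm effects anywhere: equal costs, zero treatment effects."""
    return t.SimParams(
        seed=seed,
        cost_scale_by_category_and_arm=equal_arm_scales(),
        phq_treatment_effect=0.0,
        utility_treatment_effect=0.0,
        **kw,
    )


def full_panel(dataset, unit_costs=None, ledger=None):
    """LOCF + costing + all scenarios; returns (complete_dataset, panel)."""
    complete = t.locf_impute(dataset)
    panel = t.annualize_resource_use(complete, unit_costs or t.default_unit_cost_table())
    t.build_all_scenarios(panel, ledger or t.default_programme_ledger())
    return complete, panel
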