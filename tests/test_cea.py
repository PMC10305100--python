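"""Bootstrap ICER engine, NMB regression, CEAC: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.formula.api as smf

import trialcea as t
from trialcea import cea

from helpers import full_panel, make_trial, null_params, scaled_control_scales


@pytest.fixture(scope="module")
def dominance_analysis():
    """Intervention overwhelmingly better and cheaper, tiny noise."""
    trial = make_trial(
        n_int=25,
        n_ctl=25,
        n_sites=1,
        seed=21,
        dropout=0.0,
        phq_treatment_effect=-10.0,
        phq_noise_sd=0.3,
        cost_shape=20.0,
        use_probability=1.0,
        cost_scale_by_category_and_arm={
            cat: {"intervention": s["intervention"] / 25.0, "control": s["intervention"] / 5.0}
            for cat, s in scaled_control_scales(1.0).items()
        },
    )
    return full_panel(trial)


def test_forced_dominance_fills_south_east(dominance_analysis):
    complete, panel = dominance_analysis
    res = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=300, seed=4)
    assert res.quadrant_shares["SE"] == 1.0
    assert sum(res.quadrant_shares.values()) == pytest.approx(1.0, abs=1e-9)


def test_bootstrap_reproducible_and_seed_sensitive(small_analysis):
    complete, panel = small_analysis
    a = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=150, seed=5)
    b = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=150, seed=5)
    c = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=150, seed=6)
    np.testing.assert_array_equal(a.delta_costs, b.delta_costs)
    np.testing.assert_array_equal(a.delta_effects, b.delta_effects)
    assert not np.array_equal(a.delta_costs, c.delta_costs)


def test_bootstrap_engine_matches_naive_loop():
    """Replicate-for-replicate equivalence with an independent OLS loop."""
    trial = make_trial(n_int=10, n_ctl=10, n_sites=2, seed=13, dropout=0.0)
    complete, panel = full_panel(trial)
    seed, n_reps = 99, 200
    engine = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=n_reps, seed=seed)

    frame = cea.analysis_frame(complete, panel, "phq9", "base")
    int_rows = np.flatnonzero(frame["arm_ind"] == 1.0)
    ctl_rows = np.flatnonzero(frame["arm_ind"] == 0.0)
    rng = np.random.default_rng(seed)
    dc = np.empty(n_reps)
    de = np.empty(n_reps)
    for r in range(n_reps):
        rows = np.concatenate(
            [
                int_rows[rng.integers(0, len(int_rows), len(int_rows))],
                ctl_rows[rng.integers(0, len(ctl_rows), len(ctl_rows))],
            ]
        )
        sub = frame.iloc[rows]
        fml = "{} ~ arm_ind + age + male + C(site) + baseline_cost + baseline"
        dc[r] = smf.ols(fml.format("cost"), data=sub).fit().params["arm_ind"]
        de[r] = smf.ols(fml.format("value_hib"), data=sub).fit().params["arm_ind"]
    np.testing.assert_allclose(engine.delta_costs, dc, rtol=1e-7, atol=1e-7)
    np.testing.assert_allclose(engine.delta_effects, de, rtol=1e-7, atol=1e-9)


def test_bootstrap_recovers_injected_truth():
    """Bootstrap means track true dC=-400, dE=+2 within Monte-Carlo error."""
    design = t.TrialDesign(n_intervention=81, n_control=68, n_sites=2)
    scales = scaled_control_scales(1.0)
    factor = (1401.1 + 400.0) / 1401.1  # control costs 400 euros/year higher
    for cat in scales:
        scales[cat]["control"] = scales[cat]["intervention"] * factor
    table = t.default_unit_cost_table()
    mean_dc, mean_de = [], []
    params0 = t.SimParams(
        cost_scale_by_category_and_arm=scales,
        phq_treatment_effect=-2.0,
        dropout_prob_per_occasion=0.0,
        site_cost_multipliers=(0.9, 1.1),
    )
    gt = t.ground_truth(design, params0)
    assert gt.true_delta_cost == pytest.approx(-400.0, abs=0.01)
    ledger = t.default_programme_ledger()
    # base-scenario totals add the per-capita programme cost to the
    # intervention arm, shifting the true cost difference accordingly
    truth_dc_base = gt.true_delta_cost + t.per_capita_programme_cost(ledger, "itt")
    for seed in range(50):
        params = t.SimParams(**{**params0.__dict__, "seed": seed})
        trial = t.simulate_trial(design, params)
        panel = t.annualize_resource_use(trial, table)
        t.build_all_scenarios(panel, ledger)
        res = t.bootstrap_icer(trial, panel, "phq9", "base", n_reps=200, seed=seed)
        mean_de.append(res.mean_delta_effect)
        mean_dc.append(res.mean_delta_cost)
    for est, truth in ((mean_dc, truth_dc_base), (mean_de, gt.true_delta_phq_reduction)):
        est = np.asarray(est)
        z = (est.mean() - truth) / (est.std(ddof=1) / np.sqrt(len(est)))
        assert abs(z) < 3


def test_degenerate_effect_replicates_excluded():
    # constant endpoint -> every replicate has dE == 0
    trial = make_trial(n_int=6, n_ctl=6, n_sites=1, dropout=0.0, seed=2)
    df = trial.data.copy()
    df["phq9"] = 17.0
    complete, panel = full_panel(t.TrialDataset(df, trial.design))
    res = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=50, seed=1)
    assert res.n_degenerate == 50
    assert np.isnan(res.mean_icer)
    assert sum(res.quadrant_shares.values()) == pytest.approx(1.0)


class TestNMB:
    def test_at_zero_wtp_inmb_is_negative_adjusted_cost(self, small_analysis):
        complete, panel = small_analysis
        res = t.nmb_regression(complete, panel, "phq9", "base", 0.0)
        frame = cea.analysis_frame(complete, panel, "phq9", "base")
        fit = smf.ols(
            "cost ~ arm_ind + age + male + C(site) + baseline_cost + baseline", data=frame
        ).fit()
        assert res.inmb == pytest.approx(-fit.params["arm_ind"], rel=1e-9)
        assert res.ci_low <= res.inmb <= res.ci_high

    def test_linearity_in_wtp(self, small_analysis):
        complete, panel = small_analysis
        r0 = t.nmb_regression(complete, panel, "phq9", "base", 100.0)
        r1 = t.nmb_regression(complete, panel, "phq9", "base", 700.0)
        eff = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=1, seed=0)
        assert r1.inmb - r0.inmb == pytest.approx(600.0 * eff.delta_effect_adj, rel=1e-9)

    def test_x_intercept_equals_adjusted_icer(self, small_analysis):
        complete, panel = small_analysis
        icer = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=1, seed=0)
        r0 = t.nmb_regression(complete, panel, "phq9", "base", 0.0)
        r1 = t.nmb_regression(complete, panel, "phq9", "base", 1.0)
        slope = r1.inmb - r0.inmb
        assert t.nmb_line_root(r0.inmb, slope) == pytest.approx(icer.adjusted_icer, rel=1e-9)

    def test_reference_line_root_matches_reported_rounding(self):
        # a published worked example: intercept 354.3, slope 1.97 -> root
        # -179.8, equal to the reported -180.1 to printed rounding
        root = t.nmb_line_root(354.3, 1.97)
        assert root == pytest.approx(-179.85, abs=0.01)
        assert root == pytest.approx(-180.1, abs=0.5)

    def test_negative_wtp_rejected(self, small_analysis):
        complete, panel = small_analysis
        with pytest.raises(ValueError):
            t.nmb_regression(complete, panel, "phq9", "base", -5.0)


class TestCEAC:
    def test_dominance_accepts_everywhere(self, dominance_analysis):
        complete, panel = dominance_analysis
        curve = t.ceac(complete, panel, "phq9", "base", np.arange(0.0, 501.0, 50.0))
        probs = [r.acceptance_probability for r in curve.results]
        assert min(probs) >= 0.999
        assert curve.threshold_confident == 0.0
        assert curve.prob_at_zero >= 0.999

    def test_null_acceptance_probability_near_half(self):
        """Mean acceptance ~= 0.5 at every WTP under the null (100 seeds)."""
        design = t.TrialDesign(n_intervention=40, n_control=40, n_sites=2)
        table = t.default_unit_cost_table()
        # a free programme: no effect and no cost difference anywhere
        ledger = t.ProgrammeCostLedger(0.0, 0.0, 0.0, n_participants_itt=40)
        lams = (0.0, 500.0, 1500.0)
        probs = {lam: [] for lam in lams}
        for seed in range(100):
            trial = t.simulate_trial(design, null_params(seed, dropout_prob_per_occasion=0.0))
            panel = t.annualize_resource_use(trial, table)
            t.build_all_scenarios(panel, ledger)
            for lam in lams:
                probs[lam].append(
                    t.nmb_regression(trial, panel, "phq9", "base", lam).acceptance_probability
                )
        for lam in lams:
            assert np.mean(probs[lam]) == pytest.approx(0.5, abs=0.1)

    def test_threshold_interpolation_matches_dense_scan(self, small_analysis):
        complete, panel = small_analysis
        coarse = t.ceac(complete, panel, "phq9", "base", np.arange(0.0, 2001.0, 50.0))
        dense = t.ceac(complete, panel, "phq9", "base", np.arange(0.0, 2001.0, 1.0))
        if coarse.threshold_confident is None:
            assert dense.threshold_confident is None
        else:
            assert coarse.threshold_confident == pytest.approx(
                dense.threshold_confident, abs=2.0
            )

    def test_large_wtp_asymptote_is_effect_only_probability(self, small_analysis):
        complete, panel = small_analysis
        res = t.nmb_regression(complete, panel, "phq9", "base", 1e9)
        frame = cea.analysis_frame(complete, panel, "phq9", "base")
        fit = smf.ols(
            "value_hib ~ arm_ind + age + male + C(site) + baseline_cost + baseline",
            data=frame,
        ).fit()
        p_eff = scipy.stats.t.cdf(fit.params["arm_ind"] / fit.bse["arm_ind"], fit.df_resid)
        assert res.acceptance_probability == pytest.approx(p_eff, abs=0.02)

    def test_grid_validation(self, small_analysis):
        complete, panel = small_analysis
        with pytest.raises(ValueError):
            t.ceac(complete, panel, "phq9", "base", [])
        with pytest.raises(ValueError):
            t.ceac(complete, panel, "phq9", "base", [10.0, 10.0])


class TestCEPlane:
    def _result_with_cloud(self, de, dc):
        de = np.asarray(de, dtype=float)
        dc = np.asarray(dc, dtype=float)
        return cea.ICERResult(
            endpoint="phq9",
            scenario="base",
            n_reps=de.size,
            seed=0,
            mean_icer=0.0,
            ci_low=0.0,
            ci_high=0.0,
            quadrant_shares=cea._quadrant_shares(de, dc),
            delta_costs=dc,
            delta_effects=de,
        )

    def test_symmetric_cloud_quarters(self):
        res = self._result_with_cloud([1, 1, -1, -1], [1, -1, -1, 1])
        assert res.quadrant_shares == {"NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25}

    def test_export_roundtrip(self, small_analysis):
        complete, panel = small_analysis
        res = t.bootstrap_icer(complete, panel, "phq9", "base", n_reps=100, seed=3)
        table = t.ce_plane_export(res)
        shares = table["quadrant"].value_counts(normalize=True).to_dict()
        for q, share in res.quadrant_shares.items():
            assert shares.get(q, 0.0) == pytest.approx(share)
        assert table.attrs["quadrant_shares"] == res.quadrant_shares

    def test_empty_cloud_rejected(self):
        res = self._result_with_cloud([], [])
        with pytest.raises(ValueError):
            t.ce_plane_export(res)
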