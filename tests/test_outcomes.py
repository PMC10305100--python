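"""Endpoints: LOCF, WHOQOL scoring, utilities, QALYs, adjusted effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import trialcea as t
from trialcea.outcomes import SingularModelError
from trialcea.simulate import REVERSE_ITEMS

from helpers import make_trial


def _scored_items(level):
    """26 raw responses that all score as ``level`` after reverse-handling."""
    items = np.full(26, float(level))
    for i in REVERSE_ITEMS:
        items[i - 1] = 6 - level
    return items


class TestLOCF:
    def test_fully_observed_unchanged(self):
        trial = make_trial(dropout=0.0, seed=5)
        out = t.locf_impute(trial)
        pd.testing.assert_frame_equal(
            out.data[trial.data.columns], trial.data
        )
        assert not out.data["imputed"].any()

    def test_carries_last_observation_forward(self):
        trial = make_trial(n_int=2, n_ctl=2, n_sites=1, dropout=0.0, seed=1)
        df = trial.data.copy()
        pid = df["pid"].iloc[0]
        t1_value = df.loc[(df["pid"] == pid) & (df["week"] == 12), "phq9"].iloc[0]
        late = (df["pid"] == pid) & (df["week"] > 12)
        df.loc[late, "observed"] = False
        out = t.locf_impute(t.TrialDataset(df, trial.design))
        filled = out.data.loc[(out.data["pid"] == pid) & (out.data["week"] > 12)]
        assert (filled["phq9"] == t1_value).all()
        assert filled["imputed"].all()

    def test_idempotent(self, trial_small):
        once = t.locf_impute(trial_small)
        twice = t.locf_impute(once)
        pd.testing.assert_frame_equal(once.data, twice.data[once.data.columns])

    def test_missing_baseline_rejected(self, trial_small):
        df = trial_small.data.copy()
        df.loc[(df["pid"] == df["pid"].iloc[0]) & (df["week"] == 0), "observed"] = False
        with pytest.raises(ValueError, match="baseline"):
            t.locf_impute(t.TrialDataset(df, trial_small.design))

    def test_non_monotone_rejected(self):
        trial = make_trial(n_int=2, n_ctl=2, n_sites=1, dropout=0.0)
        df = trial.data.copy()
        pid = df["pid"].iloc[0]
        df.loc[(df["pid"] == pid) & (df["week"] == 12), "observed"] = False
        with pytest.raises(ValueError, match="monotone"):
            t.locf_impute(t.TrialDataset(df, trial.design))


class TestWHOQOL:
    @pytest.mark.parametrize("level,expected", [(5, 100.0), (1, 0.0), (3, 50.0)])
    def test_uniform_items_map_linearly(self, level, expected):
        domains = t.bref_to_domains(_scored_items(level))
        assert domains.to_numpy() == pytest.approx(expected)

    def test_out_of_range_items_rejected(self):
        bad = np.full(26, 3.0)
        bad[5] = 6
        with pytest.raises(ValueError):
            t.bref_to_domains(bad)
        bad[5] = 2.5
        with pytest.raises(ValueError):
            t.bref_to_domains(bad)

    def test_utility_examples(self):
        assert t.domains_to_utility([[0, 0, 0, 0]]) == pytest.approx(0.0)
        assert t.domains_to_utility([[100, 100, 100, 100]]) == pytest.approx(1.0)
        assert t.domains_to_utility([[40, 60, 50, 50]]) == pytest.approx(0.50)

    @given(
        base=arrays(float, 4, elements=st.floats(0, 100)),
        bump=arrays(float, 4, elements=st.floats(0, 50)),
    )
    def test_utility_monotone_in_every_domain(self, base, bump):
        higher = np.minimum(base + bump, 100.0)
        assert t.domains_to_utility([higher])[0] >= t.domains_to_utility([base])[0] - 1e-12

    def test_custom_weights(self):
        u = t.domains_to_utility([[100, 0, 0, 0]], weights=[1, 0, 0, 0])
        assert u == pytest.approx(1.0)
        with pytest.raises(ValueError):
            t.domains_to_utility([[50, 50, 50, 50]], weights=[1, 1, 0, 0])


class TestQALY:
    WEEKS = (0, 12, 24, 48)

    def test_flat_curve_identity(self):
        for u in (0.0, 0.3, 1.0):
            assert t.qaly_12m([[u] * 4], self.WEEKS) == pytest.approx(u)

    def test_hand_trapezoid(self):
        got = t.qaly_12m([[0.4, 0.6, 0.6, 0.6]], self.WEEKS)
        expected = (12 * 0.5 + 12 * 0.6 + 24 * 0.6 + 4 * 0.6) / 52
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.5769, abs=5e-5)

    def test_step_method(self):
        got = t.qaly_12m([[0.4, 0.6, 0.6, 0.6]], self.WEEKS, method="step")
        assert got == pytest.approx((12 * 0.4 + 12 * 0.6 + 24 * 0.6 + 4 * 0.6) / 52)

    @given(u=arrays(float, 4, elements=st.floats(0, 1)))
    def test_bounded_by_trajectory_extremes(self, u):
        q = t.qaly_12m([u], self.WEEKS)[0]
        assert u.min() - 1e-12 <= q <= u.max() + 1e-12


class TestAdjustedEffect:
    def _mirrored_trial(self):
        """Control arm an exact copy of the intervention arm."""
        trial = make_trial(n_int=30, n_ctl=2, n_sites=2, dropout=0.0, seed=9)
        df = trial.data[trial.data["arm"] == "intervention"].copy()
        mirror = df.copy()
        mirror["arm"] = "control"
        mirror["pid"] = mirror["pid"] + "c"
        data = pd.concat([df, mirror], ignore_index=True)
        design = t.TrialDesign(n_intervention=30, n_control=30, n_sites=2)
        return t.TrialDataset(data, design)

    def test_identical_arms_give_zero_effect(self):
        eff = t.adjusted_effect(self._mirrored_trial(), "phq9")
        assert eff.B == pytest.approx(0.0, abs=1e-8)
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_location_invariance(self, trial_small):
        complete = t.locf_impute(trial_small)
        eff = t.adjusted_effect(complete, "phq9")
        shifted = complete.data.copy()
        shifted.loc[shifted["week"] > 0, "phq9"] += 3.0
        eff2 = t.adjusted_effect(t.TrialDataset(shifted, complete.design), "phq9")
        assert eff2.B == pytest.approx(eff.B, abs=1e-9)

    def test_reduction_scale_flips_sign(self, trial_small):
        eff = t.adjusted_effect(t.locf_impute(trial_small), "phq9")
        red = eff.as_reduction()
        assert red.B == -eff.B
        assert red.ci_low == -eff.ci_high and red.ci_high == -eff.ci_low

    def test_singular_design_reported(self):
        trial = make_trial(n_int=5, n_ctl=5, n_sites=1, dropout=0.0)
        df = trial.data.copy()
        df["age"] = 30.0  # constant covariate -> collinear with intercept
        with pytest.raises(SingularModelError):
            t.adjusted_effect(t.TrialDataset(df, trial.design), "phq9")

    def test_recovery_coverage_of_built_in_shift(self):
        """95% CI covers the injected -2.0 shift in >= 93/100 trials."""
        design = t.TrialDesign(n_intervention=500, n_control=500, n_sites=7)
        hits = 0
        for seed in range(100):
            params = t.SimParams(
                seed=seed, phq_treatment_effect=-2.0, dropout_prob_per_occasion=0.0
            )
            eff = t.adjusted_effect(t.simulate_trial(design, params), "phq9")
            hits += eff.ci_low <= -2.0 <= eff.ci_high
        assert hits >= 93


def test_qaly_endpoint_table_bounds(small_analysis):
    complete, _ = small_analysis
    tab = t.endpoint_table(complete, "qaly")
    assert tab["value"].between(0, 1).all()
    assert (tab["value_hib"] == tab["value"]).all()
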