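"""Outcome merging, collinearity screening, proportional-odds fitting and
AIC-stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from breastcomp import (
    collinearity_filter,
    endpoint_sweep,
    fit_ordinal,
    merge_outcomes,
    simulate_ordinal_outcomes,
    stepwise_aic,
)
from breastcomp.association import FitError


def _po_frame(n, beta, seed, n_null=0, cutpoints=(-1.0, 1.0, 2.5)):
    """Proportional-odds data with one true covariate and optional nulls."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1 + n_null))
    y = simulate_ordinal_outcomes(x, np.r_[beta, np.zeros(n_null)], cutpoints, rng)
    cols = {"x0": x[:, 0], **{f"null{j}": x[:, 1 + j] for j in range(n_null)}}
    return pd.DataFrame({"grade": y, **cols})


class TestMergeOutcomes:
    @pytest.mark.parametrize(
        "cro,pro,expected,who",
        [
            (1, 2, 2, "pro"),
            (0, 0, 0, "tie"),
            (3, np.nan, 3, "cro"),
            (np.nan, 1, 1, "pro"),
        ],
    )
    def test_max_merge_with_provenance(self, cro, pro, expected, who):
        merged, prov = merge_outcomes([cro], [pro])
        assert merged.iloc[0] == expected
        assert prov.iloc[0] == who

    def test_both_missing_stays_missing(self):
        merged, prov = merge_outcomes([np.nan], [np.nan])
        assert np.isnan(merged.iloc[0])
        assert prov.iloc[0] == "missing"


class TestCollinearityFilter:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        retained, decisions = collinearity_filter(df, ["a", "b"])
        assert retained == ["a"]
        assert decisions[0]["dropped"] == "b" and decisions[0]["r"] == pytest.approx(1.0)

    def test_independent_gaussians_survive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 6)), columns=list("abcdef"))
        retained, _ = collinearity_filter(df, list("abcdef"))
        assert retained == list("abcdef")

    def test_near_duplicate_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["x_noisy"] = df["x"] + rng.normal(0, 0.01, 200)
        assert abs(df["x"].corr(df["x_noisy"])) >= 0.9
        retained, _ = collinearity_filter(df, ["x", "x_noisy"])
        assert retained == ["x"]

    def test_zero_variance_dropped_with_reason(self):
        df = pd.DataFrame({"c": np.ones(30), "x": np.arange(30.0)})
        retained, decisions = collinearity_filter(df, ["c", "x"])
        assert retained == ["x"]
        assert decisions[0]["reason"] == "zero variance"

    def test_scorer_decides_which_to_keep(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        df["b"] = df["a"] * 1.0001
        retained, _ = collinearity_filter(df, ["a", "b"], scorer={"a": 5, "b": 1}.get)
        assert retained == ["b"]


class TestFitOrdinal:
    def test_aic_identity(self):
        df = _po_frame(400, beta=0.8, seed=0)
        fit = fit_ordinal(df, "grade", ["x0"])
        assert fit.aic == pytest.approx(
            2 * (len(fit.params) + len(fit.cutpoints)) - 2 * fit.log_likelihood, abs=1e-9
        )
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_coefficient_recovery(self):
        df = _po_frame(2000, beta=0.8, seed=1)
        fit = fit_ordinal(df, "grade", ["x0"])
        assert fit.converged
        assert fit.params["x0"] == pytest.approx(0.8, abs=0.15)
        # Wald CI covers the truth
        lo = fit.params["x0"] - 1.96 * fit.bse["x0"]
        hi = fit.params["x0"] + 1.96 * fit.bse["x0"]
        assert lo < 0.8 < hi

    def test_single_level_outcome_rejected(self):
        df = pd.DataFrame({"grade": np.zeros(50, int), "x0": np.arange(50.0)})
        with pytest.raises(FitError, match="single observed level"):
            fit_ordinal(df, "grade", ["x0"])

    def test_missing_rows_excluded(self):
        df = _po_frame(300, beta=0.5, seed=2)
        df.loc[:49, "x0"] = np.nan
        fit = fit_ordinal(df, "grade", ["x0"])
        assert fit.n_used == 250


class TestStepwise:
    def test_no_candidates_returns_baseline_exactly(self):
        df = _po_frame(500, beta=0.8, seed=3)
        trace, fit = stepwise_aic(df, "grade", baseline=["x0"], candidates=[], direction="forward")
        assert trace.final_variables == ("x0",)
        assert fit.aic == pytest.approx(trace.baseline_aic, abs=1e-9)

    def test_true_effect_selected_over_nulls(self):
        df = _po_frame(1500, beta=1.0, seed=4, n_null=5)
        trace, fit = stepwise_aic(
            df, "grade", baseline=[], candidates=["x0"] + [f"null{j}" for j in range(5)]
        )
        assert "x0" in trace.final_variables

    def test_accepted_steps_strictly_decrease_aic(self):
        df = _po_frame(800, beta=1.0, seed=5, n_null=3)
        trace, _ = stepwise_aic(
            df, "grade", baseline=[], candidates=["x0"] + [f"null{j}" for j in range(3)]
        )
        for step in trace.steps:
            if step.accepted:
                assert step.aic_after < step.aic_before

    def test_forward_backward_agree_on_clear_signal(self):
        df = _po_frame(1500, beta=1.0, seed=6, n_null=3)
        cands = ["x0"] + [f"null{j}" for j in range(3)]
        f_trace, _ = stepwise_aic(df, "grade", [], cands, "forward")
        b_trace, _ = stepwise_aic(df, "grade", [], cands, "backward")
        assert set(f_trace.final_variables) == set(b_trace.final_variables)

    def test_selection_is_deterministic(self):
        df = _po_frame(600, beta=0.8, seed=7, n_null=4)
        cands = ["x0"] + [f"null{j}" for j in range(4)]
        t1, f1 = stepwise_aic(df, "grade", [], cands)
        t2, f2 = stepwise_aic(df, "grade", [], cands)
        assert t1.final_variables == t2.final_variables
        assert f1.aic == f2.aic


class TestEndpointSweep:
    def test_degenerate_cell_skipped(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "pain_post_rt": np.zeros(100, int),  # constant grade
                "oedema_post_rt": rng.integers(0, 3, 100),
                "age": rng.normal(60, 8, 100),
                "dose": rng.normal(40, 3, 100),
            }
        )
        sweep = endpoint_sweep(
            df, baseline=["age"], candidates=["dose"],
            endpoints=("pain", "oedema"), timepoints=("post_rt",), check_backward=False,
        )
        pain = sweep[sweep.endpoint == "pain"].iloc[0]
        assert pain["skipped"] == "single level"
        oedema = sweep[sweep.endpoint == "oedema"].iloc[0]
        assert oedema["skipped"] == ""
        assert oedema["best_aic"] <= oedema["baseline_aic"] + 1e-9
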