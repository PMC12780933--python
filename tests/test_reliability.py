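import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gstudy.design import RESIDUAL
from gstudy.reliability import (
    INTER_ERROR,
    INTRA_ERROR,
    SDC_FACTOR,
    g_coefficient,
    g_confidence_interval,
    interpret_g,
    reliability_table,
    results_to_frame,
    sdc,
    sdc_percent,
    sem,
)
from gstudy.simulate import SimulationSpec, preset_spec, simulate_study
from gstudy.varcomp import ModelSpec, VarianceComponents, reml_estimate
from tests.conftest import crossed_design, make_table


def vc(estimates: dict, **kw) -> VarianceComponents:
    return VarianceComponents(estimates=estimates, grand_mean=2.0, method="anova_ems", **kw)


ALL_LABELS = ("p",) + INTER_ERROR + (RESIDUAL,)

component_maps = st.fixed_dictionaries(
    {label: st.floats(min_value=0.0, max_value=2.0) for label in ALL_LABELS}
)


class TestGCoefficient:
    @pytest.mark.parametrize(
        "estimates, mode, expected",
        [
            ({"p": 1.0, RESIDUAL: 1.0}, "intra", 0.5),
            ({"p": 0.37}, "intra", 1.0),
            ({"p": 0.36, "o": 0.01, "po": 0.02, RESIDUAL: 0.06, "r": 0.0}, "intra", 0.8),
            (
                {
                    "p": 0.36,
                    "o": 0.01,
                    "po": 0.02,
                    RESIDUAL: 0.06,
                    "r": 0.0,
                    "ob": 0.05,
                    "pob": 0.04,
                },
                "inter",
                0.36 / 0.54,
            ),
        ],
    )
    def test_hand_examples(self, estimates, mode, expected):
        assert g_coefficient(vc(estimates), mode) == pytest.approx(expected)

    def test_zero_participant_variance_gives_zero(self):
        assert g_coefficient(vc({"p": 0.0, RESIDUAL: 0.3})) == 0.0

    def test_constant_data_is_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            g_coefficient(vc({"p": 0.0, RESIDUAL: 0.0}))

    def test_observer_terms_ignored_in_intra_mode(self):
        with_ob = vc({"p": 0.4, RESIDUAL: 0.1, "ob": 5.0, "pob": 3.0})
        without = vc({"p": 0.4, RESIDUAL: 0.1})
        assert g_coefficient(with_ob, "intra") == g_coefficient(without, "intra")


class TestSem:
    def test_zero_error_gives_zero(self):
        assert sem(vc({"p": 0.5})) == 0.0

    def test_hand_example(self):
        est = vc({"r": 0.0, "o": 0.01, "pr": 0.0, "po": 0.02, "ro": 0.0, RESIDUAL: 0.06})
        assert sem(est, "intra") == pytest.approx(0.3)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(component_maps)
    def test_g_sem_identity(self, estimates):
        """G = sigma2_p / (sigma2_p + SEM^2) for both modes."""
        est = vc(estimates)
        for mode in ("intra", "inter"):
            s = sem(est, mode)
            denom = estimates["p"] + s**2
            if denom == 0:
                continue
            assert g_coefficient(est, mode) == pytest.approx(
                estimates["p"] / denom, rel=1e-12, abs=1e-12
            )


class TestSdc:
    @pytest.mark.parametrize(
        "sem_cm, expected_2dp",
        [(0.20, 0.55), (0.06, 0.17), (0.07, 0.19), (0.13, 0.36), (0.0, 0.0)],
    )
    def test_published_and_degenerate_rows(self, sem_cm, expected_2dp):
        assert round(sdc(sem_cm), 2) == pytest.approx(expected_2dp)

    def test_unit_sem(self):
        assert sdc(1.0) == pytest.approx(2.772, abs=5e-4)

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            sdc(-0.1)

    @pytest.mark.parametrize(
        "sdc_cm, mean_cm, expected_int",
        [(1.06, 3.85, 28), (1.07, 2.31, 46), (0.0, 2.0, 0)],
    )
    def test_percent(self, sdc_cm, mean_cm, expected_int):
        assert round(sdc_percent(sdc_cm, mean_cm)) == expected_int

    def test_percent_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            sdc_percent(1.0, 0.0)


class TestInterpretG:
    @pytest.mark.parametrize(
        "g, band",
        [
            (0.48, "poor"),
            (0.50, "poor"),
            (0.51, "moderate"),
            (0.72, "moderate"),
            (0.75, "good"),
            (0.89, "good"),
            (0.90, "excellent"),
            (0.95, "excellent"),
            (0.0, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_bands(self, g, band):
        assert interpret_g(g) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_g(1.2)


class TestMonotonicity:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(component_maps, st.sampled_from(sorted(INTER_ERROR)), st.floats(0.01, 1.0))
    def test_adding_error_decreases_g_increases_sem(self, estimates, label, extra):
        if estimates["p"] + sum(estimates[c] for c in INTER_ERROR) + estimates[RESIDUAL] == 0:
            return
        base = vc(dict(estimates))
        bumped_est = dict(estimates)
        bumped_est[label] += extra
        bumped = vc(bumped_est)
        assert g_coefficient(bumped, "inter") <= g_coefficient(base, "inter") + 1e-12
        assert sem(bumped, "inter") >= sem(base, "inter") - 1e-12

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(component_maps)
    def test_inter_g_never_exceeds_intra_g(self, estimates):
        est = vc(estimates)
        total = sum(estimates.values())
        if total == 0:
            return
        assert g_coefficient(est, "inter") <= g_coefficient(est, "intra") + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(component_maps, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, estimates, k):
        """Scaling thickness by k: G and %SDC invariant, SEM/SDC scale by k."""
        if sum(estimates.values()) == 0:
            return
        base = vc(dict(estimates))
        scaled = vc({c: k**2 * v for c, v in estimates.items()})
        assert g_coefficient(scaled, "inter") == pytest.approx(
            g_coefficient(base, "inter"), rel=1e-9, abs=1e-12
        )
        assert sem(scaled, "inter") == pytest.approx(k * sem(base, "inter"), rel=1e-9)
        s = sem(base, "inter")
        mean = 2.0
        assert sdc_percent(sdc(k * s), k * mean) == pytest.approx(
            sdc_percent(sdc(s), mean), rel=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.0, max_value=5.0))
    def test_sdc_sem_ratio_is_fixed(self, s):
        assert sdc(s) == pytest.approx(SDC_FACTOR * s, rel=1e-15)


class TestConfidenceInterval:
    def test_zero_error_collapses_to_one(self):
        import pandas as pd

        est = vc({"p": 0.4, RESIDUAL: 0.0})
        est.cov = pd.DataFrame(
            np.eye(2) * 1e-4, index=["p", RESIDUAL], columns=["p", RESIDUAL]
        )
        lo, hi = g_confidence_interval(est, method="wald_delta")
        assert (lo, hi) == (1.0, 1.0)

    def test_upper_limit_clamped_at_one(self, sci_table):
        fit = reml_estimate(sci_table, model=ModelSpec(frozenset({"p", "r"})))
        lo, hi = g_confidence_interval(fit, "intra")
        assert 0.0 <= lo <= g_coefficient(fit) <= hi <= 1.0

    def test_missing_covariance_suggests_bootstrap(self):
        est = vc({"p": 0.4, RESIDUAL: 0.1})
        with pytest.raises(ValueError, match="bootstrap"):
            g_confidence_interval(est, method="wald_delta")

    def test_bootstrap_agrees_roughly_with_wald(self, sci_table):
        model = ModelSpec(frozenset({"p", "r"}))
        fit = reml_estimate(sci_table, model=model)
        wlo, whi = g_confidence_interval(fit, "intra")
        blo, bhi = g_confidence_interval(
            fit, "intra", method="parametric_bootstrap", n_boot=200, seed=1, model=model
        )
        assert blo == pytest.approx(wlo, abs=0.03)
        assert bhi == pytest.approx(whi, abs=0.03)

    def test_small_bootstrap_warns(self, sci_table):
        model = ModelSpec(frozenset({"p", "r"}))
        fit = reml_estimate(sci_table, model=model)
        with pytest.warns(UserWarning, match="n_boot"):
            g_confidence_interval(
                fit, "intra", method="parametric_bootstrap", n_boot=60, seed=1,
                model=model,
            )


class TestReliabilityTable:
    def test_constant_muscle_errors_propagate_per_muscle(self, sci_table):
        import pandas as pd

        constant = sci_table.copy()
        constant["muscle"] = "Flat"
        constant["thickness_cm"] = 1.0
        both = pd.concat([sci_table, constant], ignore_index=True)
        results, errors = reliability_table(both, mode="intra")
        assert [r.muscle for r in results] == ["Gmed"]
        assert "Flat" in errors

    def test_sci_preset_is_excellent(self, sci_table):
        results, errors = reliability_table(sci_table, mode="intra")
        assert not errors
        assert results[0].band == "excellent"
        assert results[0].sdc_cm == pytest.approx(SDC_FACTOR * results[0].sem_cm)
        assert 0 <= results[0].ci_low <= results[0].g <= results[0].ci_high <= 1

    def test_inter_g_below_intra_g_on_same_table(self, ab_table):
        intra, _ = reliability_table(ab_table, mode="intra", seed=0)
        inter, _ = reliability_table(ab_table, mode="inter", seed=0)
        assert inter[0].g <= intra[0].g
        assert inter[0].sem_cm >= intra[0].sem_cm

    def test_inter_mode_on_single_observer_design_fails_cleanly(self, sci_table):
        results, errors = reliability_table(sci_table, mode="inter")
        assert results == []
        assert "observer" in errors["Gmed"]

    def test_rounded_frame_has_table_shape(self, sci_table):
        results, _ = reliability_table(sci_table, mode="intra")
        frame = results_to_frame(results)
        assert set(["muscle", "G", "ci95", "SEM", "SDC", "pct_SDC", "band"]) <= set(
            frame.columns
        )
        assert isinstance(frame.loc[0, "pct_SDC"], (int, np.integer))
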