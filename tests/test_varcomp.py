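import subprocess

import numpy as np
import pandas as pd
import pytest

from gstudy.design import infer_design, write_measurements
from gstudy.simulate import SimulationSpec, preset_spec, simulate_study
from gstudy.varcomp import (
    ModelSpec,
    NonIdentifiableError,
    UnbalancedDataError,
    anova_ems_estimate,
    backward_simplify,
    model_consistency_check,
    model_ladder,
    reml_estimate,
)
from tests.conftest import crossed_design, make_table


class TestAnovaEms:
    def test_hand_2x2_example(self, hand_2x2):
        """MS_p=4, MS_ob=1, MS_res=0 give sigma2_p=2, sigma2_ob=0.5, res=0."""
        est = anova_ems_estimate(hand_2x2)
        assert est.estimates["p"] == pytest.approx(2.0, abs=1e-12)
        assert est.estimates["ob"] == pytest.approx(0.5, abs=1e-12)
        assert est.estimates["residual"] == pytest.approx(0.0, abs=1e-12)
        assert est.grand_mean == pytest.approx(2.5)

    def test_constant_table_gives_all_zero(self):
        table = make_table(
            {(p, ob, "1", "1"): 3.3 for p in "ABC" for ob in "12"}
        )
        est = anova_ems_estimate(table)
        assert all(v == pytest.approx(0.0, abs=1e-20) for v in est.estimates.values())

    def test_unbalanced_input_directs_to_reml(self, ab_table):
        broken = ab_table.drop(ab_table.index[0])
        with pytest.raises(UnbalancedDataError):
            anova_ems_estimate(broken, infer_design(broken))

    def test_single_level_component_rejected(self, sci_table):
        with pytest.raises(ValueError, match="single-level"):
            anova_ems_estimate(
                sci_table, model=ModelSpec(frozenset({"p", "ob"}))
            )

    def test_negative_solutions_clipped_and_flagged(self):
        # participant means nearly equal but high within-cell spread drives
        # the participant solution negative
        rng = np.random.default_rng(5)
        vals = {}
        for p in range(6):
            noise = rng.normal(0, 1.0, 4)
            noise -= noise.mean()  # exactly equal participant means
            for r, eps in enumerate(noise):
                vals[(f"P{p}", "1", "1", f"R{r}")] = 3.0 + eps
        est = anova_ems_estimate(make_table(vals))
        assert "p" in est.clipped
        assert est.estimates["p"] == 0.0

    def test_location_invariance_and_scale_equivariance(self, ab_table):
        base = anova_ems_estimate(ab_table)
        shifted = ab_table.assign(thickness_cm=ab_table["thickness_cm"] + 5.0)
        scaled = ab_table.assign(thickness_cm=ab_table["thickness_cm"] * 3.0)
        est_shift = anova_ems_estimate(shifted)
        est_scale = anova_ems_estimate(scaled)
        for c, v in base.estimates.items():
            assert est_shift.estimates[c] == pytest.approx(v, abs=1e-9)
            assert est_scale.estimates[c] == pytest.approx(9.0 * v, rel=1e-9)

    def test_relabelling_invariance(self, sci_table):
        base = anova_ems_estimate(sci_table)
        relabelled = sci_table.copy()
        relabelled["participant"] = "x_" + relabelled["participant"]
        est = anova_ems_estimate(relabelled)
        for c, v in base.estimates.items():
            assert est.estimates[c] == pytest.approx(v, abs=1e-12)

    def test_component_sum_matches_total_variance(self):
        """On balanced data the decomposition recovers the sample variance."""
        spec = SimulationSpec(
            2.0,
            {"p": 0.25, "r": 0.01, "pr": 0.03, "residual": 0.08},
            crossed_design(200, 1, 1, 3),
            seed=8,
        )
        table = simulate_study(spec)
        est = anova_ems_estimate(table)
        total = table["thickness_cm"].var(ddof=1)
        assert est.total() == pytest.approx(total, rel=0.05)


class TestReml:
    def test_matches_anova_on_hand_example(self, hand_2x2):
        a = anova_ems_estimate(hand_2x2)
        r = reml_estimate(hand_2x2)
        for c in a.estimates:
            assert r.estimates[c] == pytest.approx(a.estimates[c], abs=1e-6)

    def test_constant_table_converges_to_zero(self):
        table = make_table({(p, "1", "1", r): 2.0 for p in "ABCD" for r in "123"})
        est = reml_estimate(table)
        assert est.converged
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in est.estimates.values())

    def test_balanced_and_dense_engines_agree(self, sci_table):
        model = ModelSpec(frozenset({"p", "r"}))
        b = reml_estimate(sci_table, model=model, engine="balanced")
        d = reml_estimate(sci_table, model=model, engine="dense")
        for c in b.estimates:
            assert d.estimates[c] == pytest.approx(b.estimates[c], abs=1e-6)
        assert d.loglik == pytest.approx(b.loglik, abs=1e-5)
        assert d.grand_mean == pytest.approx(b.grand_mean, abs=1e-8)

    def test_matches_lme4_on_unbalanced_crossed_data(self, tmp_path):
        """Independent oracle: lme4 REML on an unbalanced crossed table."""
        table = simulate_study(preset_spec("ab_gmed", seed=9))
        unbalanced = table.drop(table.sample(7, random_state=1).index).reset_index(
            drop=True
        )
        fit = reml_estimate(
            unbalanced,
            infer_design(unbalanced),
            ModelSpec(frozenset({"p", "ob", "pob"})),
        )
        csv = tmp_path / "t.csv"
        write_measurements(unbalanced, csv)
        rscript = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(thickness_cm ~ 1 + (1|participant) + (1|observer)"
            " + (1|participant:observer), data=d, REML=TRUE);"
            "vc <- as.data.frame(VarCorr(m));"
            "cat(sprintf('%s=%.10f;', vc$grp, vc$vcov))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        ).stdout
        ref = {
            kv.split("=")[0].strip(): kv.split("=")[1]
            for kv in out.strip().strip(";").split(";")
            if "=" in kv
        }
        mapping = {
            "participant": "p",
            "observer": "ob",
            "participant:observer": "pob",
            "Residual": "residual",
        }
        for rname, label in mapping.items():
            assert fit.estimates[label] == pytest.approx(
                float(ref[rname]), abs=1e-5
            ), label

    def test_sci_parameter_recovery(self):
        """sigma2_p and sigma2_res recovered on the single-observer design."""
        spec = SimulationSpec(
            2.0, {"p": 0.3, "residual": 0.005}, crossed_design(30, 1, 1, 3)
        )
        rng = np.random.default_rng(77)
        model = ModelSpec(frozenset({"p"}))
        sums = {"p": 0.0, "residual": 0.0}
        n = 50
        for _ in range(n):
            est = reml_estimate(simulate_study(spec, rng=rng), model=model)
            for c in sums:
                sums[c] += est.estimates[c]
        assert sums["p"] / n == pytest.approx(0.3, rel=0.2)
        assert sums["residual"] / n == pytest.approx(0.005, rel=0.2)

    def test_aliased_components_raise_with_names(self, sci_table):
        design = infer_design(sci_table)
        aliased = ModelSpec.full(design, include_aliased=True)
        with pytest.raises(NonIdentifiableError, match="residual"):
            reml_estimate(sci_table, design, aliased)


class TestBackwardSimplify:
    def test_no_drops_when_all_components_matter(self):
        spec = SimulationSpec(
            2.5,
            {
                "p": 0.3,
                "r": 0.02,
                "o": 0.03,
                "pr": 0.04,
                "po": 0.08,
                "ro": 0.03,
                "residual": 0.1,
            },
            crossed_design(60, 1, 2, 3),
            seed=21,
        )
        table = simulate_study(spec)
        # estimate rule: nothing sits on the zero boundary, so nothing drops
        model, fit, log = backward_simplify(table, criterion="estimate")
        assert [ev for ev in log if "single-level" not in ev.reason] == []
        assert model.components == frozenset(
            {"p", "r", "o", "pr", "po", "ro", "residual"}
        )
        # likelihood rule: components too weak to detect may go, but the
        # clearly supported ones and all protected ones stay
        model_l, _fit_l, _log_l = backward_simplify(table, criterion="lrt")
        assert {"p", "r", "po", "residual"} <= model_l.components

    def test_single_level_and_aliased_components_dropped_first(self, sci_table):
        design = infer_design(sci_table)
        full = ModelSpec.full(
            crossed_design(30, 3, 2, 3), include_aliased=True
        )
        model, fit, log = backward_simplify(sci_table, design, full_model=full)
        reasons = {ev.component: ev.reason for ev in log}
        assert any("single-level" in r for r in reasons.values())
        assert "pr" in model.components or "pr" in reasons
        # the residual-aliased full interaction must be gone
        assert "proob" not in model.components

    def test_protected_components_survive(self, ab_table):
        model, fit, log = backward_simplify(ab_table, criterion="lrt")
        assert {"p", "r", "residual"} <= model.components
        assert all(ev.component not in {"p", "r", "residual"} for ev in log)

    def test_protected_single_level_component_is_design_flaw(self, sci_table):
        with pytest.raises(NonIdentifiableError, match="structurally absent"):
            backward_simplify(
                sci_table,
                full_model=ModelSpec(frozenset({"p", "r", "o"}), frozenset({"p", "o"})),
                protected=("p", "o"),
            )


class TestConsistencyCheck:
    def test_balanced_ladder_passes(self):
        spec = SimulationSpec(
            2.5,
            {"p": 0.3, "r": 0.01, "o": 0.02, "residual": 0.1},
            crossed_design(40, 1, 2, 3),
            seed=31,
        )
        table = simulate_study(spec)
        design = infer_design(table)
        report = model_consistency_check(table, design, model_ladder(design))
        assert report.passed
        assert report.max_rel_diff < 0.05

    def test_omitted_observer_terms_distort_sem(self):
        """A rung lacking observer terms leaks their variance into the
        residual, so its intra SEM disagrees with the full model's."""
        spec = SimulationSpec(
            2.5,
            {"p": 0.2, "ob": 0.3, "pob": 0.2, "residual": 0.05},
            crossed_design(40, 3, 1, 2),
            seed=32,
        )
        table = simulate_study(spec)
        design = infer_design(table)
        ladder = {
            "no-observer": ModelSpec(frozenset({"p"})),
            "full": ModelSpec(frozenset({"p", "ob", "pob"})),
        }
        report = model_consistency_check(table, design, ladder, mode="intra")
        assert report.passed is False

    def test_single_rung_reports_no_comparison(self, sci_table):
        report = model_consistency_check(
            sci_table, ladder={"only": ModelSpec(frozenset({"p", "r"}))}
        )
        assert report.passed is None
        assert report.max_rel_diff is None

    def test_failed_rung_is_reported_not_raised(self, sci_table):
        # 'pr' is the full interaction of the multi-level facets here, hence
        # aliased with the residual
        ladder = {
            "ok": ModelSpec(frozenset({"p", "r"})),
            "broken": ModelSpec(frozenset({"p", "r", "pr"})),
        }
        report = model_consistency_check(sci_table, ladder=ladder)
        assert "broken" in report.errors
        assert report.sems["ok"] is not None
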