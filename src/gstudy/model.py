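"""Model/Results interface tying the G-study pipeline together.

``GStudy`` wraps one muscle's long-format table; ``fit()`` runs backward model
simplification and REML (or the balanced ANOVA estimator) and returns a
``GStudyResults`` carrying the variance components, their asymptotic standard
errors, the reliability metrics per scenario, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reliability as rel
from .agreement import AgreementResult, bland_altman
from .design import (
    RESIDUAL,
    StudyDesign,
    infer_design,
    load_measurements,
    sort_components,
)
from .simulate import SimulationSpec, simulate_study
from .varcomp import (
    DropEvent,
    ModelSpec,
    VarianceComponents,
    anova_ems_estimate,
    backward_simplify,
    reml_estimate,
)

__all__ = ["GStudy", "GStudyResults"]


class GStudy:
    """Generalizability study of one muscle's crossed measurement table.

    Parameters
    ----------
    data : long-format table with the canonical columns
        ``participant, observer, occasion, repetition, muscle, thickness_cm``.
    muscle : select one muscle from a multi-muscle table.
    design : override the inferred :class:`StudyDesign`.

    Examples
    --------
    >>> from gstudy import GStudy, preset_spec, simulate_study
    >>> table = simulate_study(preset_spec("sci_default", seed=7))
    >>> res = GStudy(table).fit()
    >>> 0.9 < res.g("intra") <= 1.0
    True
    """

    def __init__(
        self,
        data: pd.DataFrame,
        muscle: str | None = None,
        design: StudyDesign | None = None,
    ) -> None:
        if muscle is not None:
            data = data[data["muscle"].astype(str) == str(muscle)]
        if len(data) == 0:
            raise ValueError("no records (wrong muscle label?)")
        muscles = data["muscle"].unique()
        if len(muscles) > 1:
            raise ValueError(
                f"table holds {len(muscles)} muscles {sorted(map(str, muscles))}; "
                "pass muscle=... or use reliability.reliability_table"
            )
        self.data = data.reset_index(drop=True)
        self.muscle = str(muscles[0])
        self.design = design or infer_design(self.data)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, muscle: str | None = None,
        column_map: Mapping[str, str] | None = None,
    ) -> "GStudy":
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        return cls(df, muscle=muscle)

    @classmethod
    def from_csv(
        cls, path: str, muscle: str | None = None,
        column_map: Mapping[str, str] | None = None,
    ) -> "GStudy":
        df, _design = load_measurements(path, column_map)
        return cls(df, muscle=muscle)

    def fit(
        self,
        method: Literal["reml", "anova_ems"] = "reml",
        backward: bool = True,
        criterion: Literal["estimate", "lrt"] = "lrt",
        drop_tol: float = 1e-6,
        protected: Sequence[str] | None = None,
        model: ModelSpec | None = None,
    ) -> "GStudyResults":
        if backward:
            spec, components, log = backward_simplify(
                self.data,
                self.design,
                full_model=model,
                drop_tol=drop_tol,
                protected=protected,
                method=method,
                criterion=criterion,
            )
        else:
            spec = model or ModelSpec.full(self.design)
            fit_fn = reml_estimate if method == "reml" else anova_ems_estimate
            components = fit_fn(self.data, self.design, spec)
            log = []
        return GStudyResults(self, spec, components, log)


@dataclass
class GStudyResults:
    """Fitted variance components and derived reliability metrics."""

    study: GStudy
    model_spec: ModelSpec
    components: VarianceComponents
    drop_log: list[DropEvent] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        labels = sort_components(self.components.estimates)
        return pd.Series(
            [self.components.estimates[c] for c in labels], index=labels,
            name="sigma2",
        )

    @property
    def bse(self) -> pd.Series:
        if self.components.cov is None:
            return pd.Series(np.nan, index=self.params.index, name="se")
        d = np.sqrt(np.maximum(np.diag(self.components.cov.to_numpy()), 0.0))
        se = pd.Series(d, index=self.components.cov.index, name="se")
        return se.reindex(self.params.index)

    def g(self, mode: rel.Mode = "intra") -> float:
        return rel.g_coefficient(self.components, mode)

    def sem(self, mode: rel.Mode = "intra") -> float:
        return rel.sem(self.components, mode)

    def sdc(self, mode: rel.Mode = "intra") -> float:
        return rel.sdc(self.sem(mode))

    def sdc_percent(self, mode: rel.Mode = "intra") -> float:
        mean = float(self.study.data["thickness_cm"].mean())
        return rel.sdc_percent(self.sdc(mode), mean)

    def conf_int(
        self, mode: rel.Mode = "intra", level: float = 0.95,
        method: str = "wald_delta", seed: int | None = None,
    ) -> tuple[float, float]:
        return rel.g_confidence_interval(
            self.components, mode, level=level, method=method, seed=seed,
            model=self.model_spec,
        )

    def reliability(
        self, mode: rel.Mode = "intra", level: float = 0.95,
        ci_method: str = "wald_delta", seed: int | None = None,
    ) -> rel.ReliabilityResult:
        return rel._result_for(
            self.study.data, self.study.design, self.study.muscle, mode,
            self.components, self.model_spec, ci_method, level, seed,
        )

    def bland_altman(self, predictor: str = "blup") -> AgreementResult:
        return bland_altman(self.study.data, self.study.design, predictor=predictor)

    def simulate(self, seed: int | None = None) -> pd.DataFrame:
        """Parametric re-simulation from the fitted components."""
        spec = SimulationSpec(
            grand_mean_cm=self.components.grand_mean,
            variance_map=dict(self.components.estimates),
            design=self.study.design,
            seed=seed,
            muscle=self.study.muscle,
        )
        return simulate_study(spec)

    def summary(self) -> str:
        comp = self.components
        lines = [
            "G-study variance components"
            + f" — muscle {self.study.muscle!r}, method {comp.method}",
            f"records: {comp.n_records}   grand mean: {comp.grand_mean:.4f} cm",
            f"converged: {comp.converged}"
            + (f"   REML loglik: {comp.loglik:.3f}" if comp.loglik is not None else ""),
            "",
            f"{'component':>10} {'sigma2 (cm^2)':>14} {'se':>10}",
        ]
        se = self.bse
        for label in self.params.index:
            se_txt = f"{se[label]:.5f}" if np.isfinite(se[label]) else "—"
            lines.append(f"{label:>10} {self.params[label]:>14.6f} {se_txt:>10}")
        if self.drop_log:
            lines.append("")
            lines.append("dropped components:")
            for ev in self.drop_log:
                lines.append(f"  - {ev.component}: {ev.reason}")
        lines.append("")
        for mode in ("intra", "inter"):
            if mode == "inter" and self.study.design.levels.get("observer", 1) < 2:
                continue
            try:
                g = self.g(mode)  # type: ignore[arg-type]
                s = self.sem(mode)  # type: ignore[arg-type]
                lines.append(
                    f"{mode}-observer: G={g:.3f} ({rel.interpret_g(g)})  "
                    f"SEM={s:.3f} cm  SDC={rel.sdc(s):.3f} cm  "
                    f"%SDC={self.sdc_percent(mode):.1f}"  # type: ignore[arg-type]
                )
            except ValueError as exc:
                lines.append(f"{mode}-observer: not available ({exc})")
        return "\n".join(lines)
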