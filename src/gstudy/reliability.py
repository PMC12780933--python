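"""Reliability and measurement-error metrics from variance components.

The G-coefficient is the generalizability-theory analogue of an intraclass
correlation: the ratio of the object-of-measurement (participant) variance to
the total variance relevant for a measurement scenario,

    intra-observer:  G = s_p / (s_p + s_r + s_o + s_pr + s_po + s_ro + s_res)
    inter-observer:  G = s_p / (intra denominator + s_ob + s_pob + s_rob
                                + s_oob + s_pro + s_prob + s_poob + s_proob)

(each s is a variance component; the intra-observer error excludes every term
involving the observer facet).  The standard error of measurement is the
square root of the mode's error-variance sum, the smallest detectable change
is SDC = 1.96 * sqrt(2) * SEM, and %SDC expresses the SDC relative to the
mean thickness.  Components absent from a (simplified) model contribute
exactly 0.  Note that the three-way participant x repetition x occasion term
appears only in the inter-observer denominator; the formulas are applied as
published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import RESIDUAL, StudyDesign, infer_design
from .varcomp import ModelSpec, VarianceComponents, backward_simplify

__all__ = [
    "INTRA_ERROR",
    "INTER_ERROR",
    "SDC_FACTOR",
    "ReliabilityResult",
    "g_coefficient",
    "sem",
    "sdc",
    "sdc_percent",
    "g_confidence_interval",
    "interpret_g",
    "reliability_table",
    "results_to_frame",
]

#: Error components of the intra-observer scenario (residual added implicitly).
INTRA_ERROR = ("r", "o", "pr", "po", "ro")
#: Additional error components entering the inter-observer scenario.
INTER_EXTRA = ("ob", "pob", "rob", "oob", "pro", "prob", "poob", "proob")
INTER_ERROR = INTRA_ERROR + INTER_EXTRA

SDC_FACTOR = 1.96 * math.sqrt(2.0)

Mode = Literal["intra", "inter"]


def _error_labels(mode: Mode) -> tuple[str, ...]:
    if mode == "intra":
        return INTRA_ERROR + (RESIDUAL,)
    if mode == "inter":
        return INTER_ERROR + (RESIDUAL,)
    raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")


def _error_variance(components: VarianceComponents, mode: Mode) -> float:
    return float(sum(components.get(label) for label in _error_labels(mode)))


def g_coefficient(components: VarianceComponents, mode: Mode = "intra") -> float:
    """Participant variance over participant + scenario error variance."""
    sp = components.get("p")
    err = _error_variance(components, mode)
    if sp + err <= 0:
        raise ValueError(
            "all variance components are zero (constant data); G is undefined"
        )
    return sp / (sp + err)


def sem(components: VarianceComponents, mode: Mode = "intra") -> float:
    """Standard error of measurement: sqrt of the scenario error variance."""
    return math.sqrt(_error_variance(components, mode))


def sdc(sem_cm: float) -> float:
    """Smallest detectable change at 95% confidence: 1.96 * sqrt(2) * SEM."""
    if sem_cm < 0:
        raise ValueError(f"SEM must be nonnegative, got {sem_cm!r}")
    return SDC_FACTOR * sem_cm


def sdc_percent(sdc_cm: float, mean_cm: float) -> float:
    """SDC as a percentage of the mean thickness."""
    if mean_cm <= 0:
        raise ValueError(f"mean thickness must be positive, got {mean_cm!r}")
    return 100.0 * sdc_cm / mean_cm


def interpret_g(
    g: float,
    bands: Sequence[tuple[float, str]] = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good")),
    top: str = "excellent",
) -> str:
    """Qualitative reliability band.

    Defaults follow the common convention: poor <= 0.50 (closed, as the bound
    is stated inclusively), 0.50 < moderate < 0.75, 0.75 <= good < 0.90,
    excellent >= 0.90.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"G must lie in [0, 1], got {g!r}")
    if g <= bands[0][0]:
        return bands[0][1]
    for bound, name in bands[1:]:
        if g < bound:
            return name
    return top


def _g_gradient(
    components: VarianceComponents, mode: Mode, labels: Sequence[str]
) -> np.ndarray:
    sp = components.get("p")
    err = _error_variance(components, mode)
    total = sp + err
    err_set = set(_error_labels(mode))
    grad = np.zeros(len(labels))
    for i, label in enumerate(labels):
        if label == "p":
            grad[i] = err / total**2
        elif label in err_set:
            grad[i] = -sp / total**2
    return grad


def g_confidence_interval(
    components: VarianceComponents,
    mode: Mode = "intra",
    level: float = 0.95,
    method: Literal["wald_delta", "parametric_bootstrap"] = "wald_delta",
    n_boot: int = 500,
    seed: int | None = None,
    model: ModelSpec | None = None,
) -> tuple[float, float]:
    """Confidence interval for the G-coefficient, clamped to [0, 1].

    ``wald_delta`` propagates the asymptotic covariance of the REML estimates
    through the G ratio (delta method), builds the interval on the logit scale
    — a variance-stabilising transform for a ratio bounded in (0, 1), which
    also keeps the interval inside the parameter space and corrects the
    skewness of the sampling distribution near the boundary — and
    back-transforms.  ``parametric_bootstrap`` refits on tables simulated from
    the fitted components and takes percentile limits.  Upper limits beyond
    the theoretical bound are reported as exactly 1.0.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    g = g_coefficient(components, mode)
    if method == "wald_delta":
        if components.cov is None:
            raise ValueError(
                "no asymptotic covariance available (ANOVA fit?); "
                "use method='parametric_bootstrap'"
            )
        labels = list(components.cov.index)
        grad = _g_gradient(components, mode, labels)
        var_g = float(grad @ components.cov.to_numpy() @ grad)
        se_g = math.sqrt(max(var_g, 0.0))
        if se_g == 0 or g <= 0 or g >= 1:
            return (min(max(g, 0.0), 1.0),) * 2
        z = stats.norm.ppf(0.5 + level / 2)
        logit = math.log(g / (1 - g))
        se_logit = se_g / (g * (1 - g))
        lo = 1 / (1 + math.exp(-(logit - z * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + z * se_logit)))
        return (max(lo, 0.0), min(hi, 1.0))
    if method == "parametric_bootstrap":
        from .simulate import SimulationSpec, simulate_study
        from .varcomp import _fit

        if components.design is None:
            raise ValueError("bootstrap requires the fitted design on the components")
        if n_boot < 100:
            import warnings

            warnings.warn(f"n_boot={n_boot} < 100 gives unstable limits", stacklevel=2)
        if model is None:
            model = ModelSpec(frozenset(components.estimates))
        spec = SimulationSpec(
            grand_mean_cm=components.grand_mean,
            variance_map=dict(components.estimates),
            design=components.design,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        gs = []
        for _ in range(n_boot):
            table = simulate_study(spec, rng=rng)
            try:
                refit = _fit(table, components.design, model, components.method)
                gs.append(g_coefficient(refit, mode))
            except ValueError:
                continue
        if len(gs) < max(10, n_boot // 5):
            raise RuntimeError("too many bootstrap refits failed")
        alpha = 1 - level
        lo, hi = np.quantile(gs, [alpha / 2, 1 - alpha / 2])
        return (max(float(lo), 0.0), min(float(hi), 1.0))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class ReliabilityResult:
    """One muscle x mode row of a reliability table."""

    muscle: str
    mode: Mode
    g: float
    ci_low: float
    ci_high: float
    sem_cm: float
    sdc_cm: float
    sdc_pct: float
    mean_cm: float
    sd_cm: float
    median_cm: float
    q1_cm: float
    q3_cm: float
    band: str
    n_records: int
    model_components: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "mode": self.mode,
            "g": self.g,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sem_cm": self.sem_cm,
            "sdc_cm": self.sdc_cm,
            "sdc_pct": self.sdc_pct,
            "mean_cm": self.mean_cm,
            "sd_cm": self.sd_cm,
            "median_cm": self.median_cm,
            "q1_cm": self.q1_cm,
            "q3_cm": self.q3_cm,
            "band": self.band,
            "n_records": self.n_records,
            "model_components": list(self.model_components),
        }


def _result_for(
    sub: pd.DataFrame,
    design: StudyDesign,
    muscle: str,
    mode: Mode,
    components: VarianceComponents,
    model: ModelSpec,
    ci_method: str,
    level: float,
    seed: int | None,
) -> ReliabilityResult:
    g = g_coefficient(components, mode)
    sem_cm = sem(components, mode)
    sdc_cm = sdc(sem_cm)
    y = sub["thickness_cm"].to_numpy(dtype=float)
    mean_cm = float(y.mean())
    ci_low, ci_high = g_confidence_interval(
        components, mode, level=level, method=ci_method, seed=seed, model=model
    )
    return ReliabilityResult(
        muscle=muscle,
        mode=mode,
        g=g,
        ci_low=ci_low,
        ci_high=ci_high,
        sem_cm=sem_cm,
        sdc_cm=sdc_cm,
        sdc_pct=sdc_percent(sdc_cm, mean_cm),
        mean_cm=mean_cm,
        sd_cm=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        median_cm=float(np.median(y)),
        q1_cm=float(np.percentile(y, 25)),
        q3_cm=float(np.percentile(y, 75)),
        band=interpret_g(g),
        n_records=len(y),
        model_components=tuple(sorted(model.components)),
    )


def reliability_table(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    mode: Mode = "intra",
    method: str = "reml",
    criterion: str = "lrt",
    drop_tol: float = 1e-6,
    protected: Sequence[str] | None = None,
    ci_method: str = "wald_delta",
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[list[ReliabilityResult], dict[str, str]]:
    """Full per-muscle reliability pipeline.

    Each muscle is fitted independently (backward-simplified model ->
    components -> G, CI, SEM, SDC, %SDC, descriptives, band).  Per-muscle
    failures are collected in the returned error mapping without aborting the
    remaining muscles.
    """
    results: list[ReliabilityResult] = []
    errors: dict[str, str] = {}
    for muscle, sub in records.groupby("muscle", sort=True):
        try:
            sub_design = design or infer_design(sub)
            model, components, _log = backward_simplify(
                sub,
                sub_design,
                drop_tol=drop_tol,
                protected=protected,
                method=method,
                criterion=criterion,  # type: ignore[arg-type]
            )
            if mode == "inter" and sub_design.levels.get("observer", 1) < 2:
                raise ValueError(
                    "inter-observer reliability requested but the observer "
                    "facet has a single level (structurally absent variance)"
                )
            results.append(
                _result_for(
                    sub, sub_design, str(muscle), mode, components, model,
                    ci_method, level, seed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - propagate per muscle
            errors[str(muscle)] = str(exc)
    return results, errors


def results_to_frame(
    results: Sequence[ReliabilityResult], rounded: bool = True
) -> pd.DataFrame:
    """Publication-shaped table (one row per muscle x mode).

    With ``rounded=True`` G/SEM/SDC and thickness summaries are shown to 2
    decimals and %SDC to the nearest integer; rounding is applied to the
    unrounded quantities only at this presentation step.
    """
    rows = []
    for r in results:
        if rounded:
            rows.append(
                {
                    "muscle": r.muscle,
                    "mode": r.mode,
                    "mean_sd": f"{r.mean_cm:.2f} ± {r.sd_cm:.2f}",
                    "median_iqr": f"{r.median_cm:.2f} ({r.q1_cm:.2f}-{r.q3_cm:.2f})",
                    "G": round(r.g, 2),
                    "ci95": f"({r.ci_low:.2f}-{r.ci_high:.2f})",
                    "SEM": round(r.sem_cm, 2),
                    "SDC": round(r.sdc_cm, 2),
                    "pct_SDC": int(round(r.sdc_pct)),
                    "band": r.band,
                }
            )
        else:
            rows.append(r.to_dict())
    return pd.DataFrame(rows)
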