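"""Bland-Altman agreement against mixed-model-predicted values.

For repeated-measures reliability data the classical mean-of-two-measurements
x-axis does not exist; instead each observation is compared against its
prediction from a linear mixed model with participant and observer as crossed
random effects,

    y = mu + u_participant + u_observer + e,

so every repetition contributes one point without averaging.  Predictions are
best linear unbiased predictions (BLUPs): shrunken random effects from
Henderson's mixed-model equations at the REML variance estimates.  The
differences (observed - predicted) give the bias and 1.96-SD limits of
agreement; heteroscedasticity ("funnel shape") is quantified by the
least-squares slope of |difference| on the predicted value with its two-sided
p-value — a quantitative stand-in for the usual visual inspection.  Because
repetitions of one participant share the unshrunk part of that participant's
effect, the |difference| points are clustered; the slope's p-value therefore
uses a cluster-robust (by participant) sandwich variance with t(G-1) degrees
of freedom, which keeps the test at its nominal size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import RESIDUAL, StudyDesign, infer_design
from .varcomp import ModelSpec, VarianceComponents, reml_estimate

__all__ = ["AgreementResult", "lmm_predict", "bland_altman", "plot_bland_altman"]

_MIN_RESID = 1e-10


@dataclass
class AgreementResult:
    """Per-record predictions/differences plus summary agreement statistics."""

    predicted_cm: np.ndarray
    difference_cm: np.ndarray
    bias_cm: float
    loa_low_cm: float
    loa_high_cm: float
    hetero_slope: float
    hetero_p: float
    n_records: int

    def to_dict(self) -> dict:
        return {
            "bias_cm": self.bias_cm,
            "loa_low_cm": self.loa_low_cm,
            "loa_high_cm": self.loa_high_cm,
            "hetero_slope": self.hetero_slope,
            "hetero_p": self.hetero_p,
            "n_records": self.n_records,
        }


def _blup(
    y: np.ndarray,
    codes: dict[str, np.ndarray],
    variances: dict[str, float],
    resid_var: float,
) -> tuple[float, dict[str, np.ndarray]]:
    """Solve Henderson's equations for intercept + crossed random effects."""
    n = len(y)
    resid_var = max(resid_var, _MIN_RESID)
    blocks = [np.ones((n, 1))]
    ridges = [0.0]
    names: list[tuple[str, int]] = [("_mu", 1)]
    for name, code in codes.items():
        var = variances.get(name, 0.0)
        if var <= 0:
            continue  # zero variance: effect shrunk entirely to 0
        q = int(code.max()) + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), code] = 1.0
        blocks.append(Z)
        ridges.append(resid_var / var)
        names.append((name, q))
    W = np.hstack(blocks)
    lhs = W.T @ W
    offset = 0
    for (name, q), ridge in zip(names, ridges):
        if ridge > 0:
            idx = np.arange(offset, offset + q)
            lhs[idx, idx] += ridge
        offset += q
    sol = np.linalg.solve(lhs, W.T @ y)
    mu = float(sol[0])
    effects: dict[str, np.ndarray] = {}
    offset = 1
    for name, q in names[1:]:
        effects[name] = sol[offset : offset + q]
        offset += q
    return mu, effects


def lmm_predict(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    predictor: str = "blup",
) -> np.ndarray:
    """Per-record predictions mu + u_participant + u_observer.

    Predictions are identical for all records sharing (participant, observer).
    A single observer reduces the model to a participant-only random effect
    (the single-occasion, single-observer arm); a single participant is an
    error.  ``predictor='cell_means'`` returns raw (participant, observer)
    cell means instead of shrunken effects, for sensitivity analysis.
    """
    design = design or infer_design(records)
    if records["muscle"].nunique() > 1:
        raise ValueError("agreement analysis expects a single-muscle table")
    if design.levels["participant"] < 2:
        raise ValueError("at least 2 participants are required")
    y = records["thickness_cm"].to_numpy(dtype=float)
    p_code = pd.Categorical(records["participant"]).codes.astype(np.int64)
    ob_code = pd.Categorical(records["observer"]).codes.astype(np.int64)
    has_observer = design.levels.get("observer", 1) > 1

    if predictor == "cell_means":
        key = p_code * (ob_code.max() + 1) + ob_code
        _, inv = np.unique(key, return_inverse=True)
        sums = np.bincount(inv, weights=y)
        counts = np.bincount(inv)
        return (sums / counts)[inv]
    if predictor != "blup":
        raise ValueError(f"unknown predictor {predictor!r}")

    comps = frozenset({"p", "ob"} if has_observer else {"p"})
    fit = reml_estimate(records, design, ModelSpec(comps))
    codes = {"p": p_code}
    if has_observer:
        codes["ob"] = ob_code
    mu, effects = _blup(
        y,
        codes,
        {k: fit.get(k) for k in codes},
        fit.get(RESIDUAL),
    )
    pred = np.full(len(y), mu)
    if "p" in effects:
        pred = pred + effects["p"][p_code]
    if "ob" in effects:
        pred = pred + effects["ob"][ob_code]
    return pred


def _cluster_robust_slope(
    x: np.ndarray, z: np.ndarray, clusters: np.ndarray
) -> tuple[float, float]:
    """OLS slope of z on x with a CR1 sandwich p-value, clustered."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        return 0.0, 1.0
    slope = float(xc @ z) / sxx
    resid = z - z.mean() - slope * xc
    _, codes = np.unique(clusters, return_inverse=True)
    G = int(codes.max()) + 1
    if G < 3:
        reg = stats.linregress(x, z)  # too few clusters for the sandwich
        return float(reg.slope), float(reg.pvalue)
    h = np.bincount(codes, weights=xc * resid)
    n = len(x)
    correction = (G / (G - 1)) * ((n - 1) / (n - 2))
    var = correction * float(h @ h) / sxx**2
    if var <= 0:
        return slope, 1.0
    tstat = slope / math.sqrt(var)
    pval = 2.0 * float(stats.t.sf(abs(tstat), df=G - 1))
    return slope, pval


def bland_altman(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    predictor: str = "blup",
) -> AgreementResult:
    """Differences, bias, limits of agreement and the funnel-shape check."""
    if len(records) < 3:
        raise ValueError("at least 3 records are required for limits of agreement")
    design = design or infer_design(records)
    pred = lmm_predict(records, design, predictor=predictor)
    y = records["thickness_cm"].to_numpy(dtype=float)
    diff = y - pred
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(pred) > 0 and np.ptp(np.abs(diff)) > 0:
        slope, pval = _cluster_robust_slope(
            pred, np.abs(diff), records["participant"].to_numpy()
        )
    else:
        slope, pval = 0.0, 1.0
    return AgreementResult(
        predicted_cm=pred,
        difference_cm=diff,
        bias_cm=bias,
        loa_low_cm=bias - 1.96 * sd,
        loa_high_cm=bias + 1.96 * sd,
        hetero_slope=slope,
        hetero_p=pval,
        n_records=len(y),
    )


def plot_bland_altman(result: AgreementResult, path: str) -> None:
    """Headless-safe scatter of differences vs predictions with bias/LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.predicted_cm, result.difference_cm, s=12, alpha=0.6)
    for yv, style in (
        (result.bias_cm, "-"),
        (result.loa_low_cm, "--"),
        (result.loa_high_cm, "--"),
    ):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("model-predicted thickness (cm)")
    ax.set_ylabel("observed - predicted (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
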