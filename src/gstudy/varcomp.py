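"""Variance-component estimation for fully crossed random-effects designs.

Two estimators share one interface:

``anova_ems_estimate``
    The classical balanced-design decomposition.  For every facet subset S the
    mean square MS_S is computed from marginal means, and the linear expected-
    mean-squares system E[MS_S] = sigma2_res + sum_{T >= S} (N / n_T) sigma2_T
    is solved for the components.  Negative solutions are clipped to zero and
    flagged.  Balanced designs only.

``reml_estimate``
    Restricted maximum likelihood for the Gaussian variance-component model.
    On balanced data the covariance matrix of the observations is diagonalised
    exactly by the ANOVA strata: the restricted log-likelihood reduces to

        l_R = -1/2 * sum_S df_S * (log lam_S + MS_S / lam_S) + const,

    with lam_S the stratum expectation above — an optimisation over a handful
    of parameters, independent of the number of records, maximised by L-BFGS-B
    with analytic gradients and nonnegativity bounds (boundary estimates are
    reported as exactly 0).  On unbalanced data a dense-matrix implementation
    of the standard restricted likelihood is used instead.  On balanced data
    with strictly positive ANOVA solutions the two estimators coincide.

Backward model simplification mirrors measurement-study practice: components
that contribute no meaningful variance are removed one at a time, either when
their estimate falls below an absolute threshold or when removing them leaves
the restricted likelihood essentially unchanged (likelihood-ratio rule); the
participant variance, the residual, and by default the repetition main effect
are never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .design import (
    FACET_ORDER,
    RESIDUAL,
    StudyDesign,
    component_facets,
    component_label,
    component_order,
    infer_design,
    sort_components,
)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "NonIdentifiableError",
    "UnbalancedDataError",
    "anova_ems_estimate",
    "reml_estimate",
    "backward_simplify",
    "model_consistency_check",
    "model_ladder",
    "ConsistencyReport",
]

_LAM_FLOOR = 1e-12
_BOUNDARY_TOL = 1e-10


class NonIdentifiableError(ValueError):
    """Requested components cannot be separated by the design."""

    def __init__(self, msg: str, pair: tuple[str, ...] | None = None) -> None:
        super().__init__(msg)
        self.pair = pair


class UnbalancedDataError(ValueError):
    """Raised by the balanced-only ANOVA estimator on unbalanced input."""


def default_protected(design: StudyDesign) -> frozenset[str]:
    """Participant, residual, and the repetition main effect (when present)."""
    protected = {"p", RESIDUAL}
    if design.levels.get("repetition", 1) > 1:
        protected.add("r")
    return frozenset(protected)


@dataclass(frozen=True)
class ModelSpec:
    """The set of variance components to estimate.

    ``components`` always includes the residual; ``protected`` components are
    never removed by backward simplification.
    """

    components: frozenset[str]
    protected: frozenset[str] = frozenset({"p", RESIDUAL})

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "components", frozenset(self.components) | {RESIDUAL}
        )
        object.__setattr__(
            self, "protected", frozenset(self.protected) & self.components
        )

    @property
    def facet_components(self) -> list[str]:
        return sort_components(c for c in self.components if c != RESIDUAL)

    def drop(self, label: str) -> "ModelSpec":
        if label in self.protected or label == RESIDUAL:
            raise ValueError(f"component {label!r} is protected and cannot be dropped")
        return ModelSpec(self.components - {label}, self.protected)

    @classmethod
    def full(
        cls,
        design: StudyDesign,
        include_aliased: bool = False,
        max_order: int | None = None,
        protected: Iterable[str] | None = None,
    ) -> "ModelSpec":
        """All estimable interactions of the design's multi-level facets.

        With one record per cell the full facet interaction is aliased with
        the residual and is excluded unless ``include_aliased`` is set.
        """
        facets = design.multi_level_facets
        comps: set[str] = set()
        top = len(facets) if include_aliased else len(facets) - 1
        top = min(top, max_order) if max_order is not None else top
        for k in range(1, max(top, 1) + 1):
            if k > len(facets):
                break
            for sub in combinations(facets, k):
                if k == len(facets) and not include_aliased:
                    continue
                comps.add(component_label(sub))
        if protected is None:
            protected = default_protected(design)
        return cls(frozenset(comps), frozenset(protected))


@dataclass
class VarianceComponents:
    """Estimated variance decomposition for one muscle.

    ``estimates`` maps component labels (plus ``'residual'``) to nonnegative
    variances in cm^2; ``cov`` is the asymptotic covariance of the estimates
    (REML only), indexed by the same labels; ``clipped`` lists ANOVA solutions
    that came out negative and were set to 0.
    """

    estimates: dict[str, float]
    grand_mean: float
    method: str
    converged: bool = True
    loglik: float | None = None
    cov: pd.DataFrame | None = None
    clipped: frozenset[str] = frozenset()
    n_records: int = 0
    design: StudyDesign | None = None

    def get(self, label: str) -> float:
        return float(self.estimates.get(label, 0.0))

    @property
    def labels(self) -> list[str]:
        return sort_components(self.estimates)

    def total(self) -> float:
        return float(sum(self.estimates.values()))

    def to_dict(self) -> dict:
        return {
            "estimates": {c: self.estimates[c] for c in self.labels},
            "grand_mean": self.grand_mean,
            "method": self.method,
            "converged": self.converged,
            "loglik": self.loglik,
            "clipped": sorted(self.clipped),
            "n_records": self.n_records,
        }


# ---------------------------------------------------------------------------
# balanced-data machinery
# ---------------------------------------------------------------------------


def _data_array(
    records: pd.DataFrame, design: StudyDesign
) -> tuple[np.ndarray, list[str]]:
    """Arrange a balanced single-muscle table as an ndarray, one axis per facet."""
    if records["muscle"].nunique() > 1:
        raise ValueError(
            "multiple muscles in one table; fit each muscle separately "
            "(see reliability_table)"
        )
    facets = [f for f in FACET_ORDER if f in design.facets]
    dims = [design.levels[f] for f in facets]
    if len(records) != int(np.prod(dims)):
        raise UnbalancedDataError(
            f"expected {int(np.prod(dims))} records for the full cross, "
            f"got {len(records)}"
        )
    sub = records.sort_values(facets, kind="mergesort")
    cells = sub.groupby(facets, sort=False).size()
    if (cells != 1).any():
        raise UnbalancedDataError("some design cells hold more than one record")
    for f, d in zip(facets, dims):
        if sub[f].nunique() != d:
            raise UnbalancedDataError(f"facet {f!r} level count mismatch")
    y = sub["thickness_cm"].to_numpy(dtype=float).reshape(dims)
    return y, facets


@dataclass
class _Stratum:
    facets: frozenset[str]
    df: int
    ms: float
    n_levels: int


def _anova_strata(y: np.ndarray, facets: list[str]) -> list[_Stratum]:
    """ANOVA decomposition of a balanced crossed array.

    Effects are built by inclusion-exclusion over marginal means (keepdims
    broadcasting); SS_S = (N / n_S) * sum(effect_S^2), df_S = prod(n_f - 1).
    The strata span the full (N-1)-dimensional contrast space.
    """
    dims = y.shape
    N = y.size
    multi_axes = [i for i, d in enumerate(dims) if d > 1]
    all_axes = tuple(range(y.ndim))
    effects: dict[frozenset[int], np.ndarray] = {
        frozenset(): y.mean(axis=all_axes, keepdims=True)
    }
    strata: list[_Stratum] = []
    for k in range(1, len(multi_axes) + 1):
        for axes in combinations(multi_axes, k):
            S = frozenset(axes)
            other = tuple(i for i in all_axes if i not in S)
            m = y.mean(axis=other, keepdims=True) if other else y.copy()
            eff = m.copy()
            for T, e in effects.items():
                if T < S:
                    eff = eff - e
            effects[S] = eff
            n_S = int(np.prod([dims[i] for i in S]))
            df_S = int(np.prod([dims[i] - 1 for i in S]))
            ss = (N / n_S) * float((eff**2).sum())
            strata.append(
                _Stratum(
                    facets=frozenset(facets[i] for i in S),
                    df=df_S,
                    ms=ss / df_S,
                    n_levels=n_S,
                )
            )
    return strata


def _ems_matrix(
    strata: Sequence[_Stratum],
    comps: Sequence[str],
    design: StudyDesign,
) -> np.ndarray:
    """Coefficient matrix C with lam = C @ [sigma2_comps..., sigma2_res]."""
    N = design.n_cells
    C = np.zeros((len(strata), len(comps) + 1))
    for j, label in enumerate(comps):
        T = component_facets(label)
        n_T = int(np.prod([design.levels[f] for f in T]))
        for i, st in enumerate(strata):
            if st.facets <= T:
                C[i, j] = N / n_T
    C[:, -1] = 1.0
    return C


def _check_identifiable(C: np.ndarray, labels: Sequence[str]) -> None:
    """Duplicate / collinear EMS columns mean aliased components."""
    ncol = C.shape[1]
    for i in range(ncol):
        for j in range(i + 1, ncol):
            if np.allclose(C[:, i], C[:, j], rtol=1e-10, atol=1e-12):
                raise NonIdentifiableError(
                    f"components {labels[i]!r} and {labels[j]!r} are aliased "
                    "in this design (identical expected-mean-square patterns)",
                    pair=(labels[i], labels[j]),
                )
    if np.linalg.matrix_rank(C) < ncol:
        raise NonIdentifiableError(
            f"components {list(labels)} are collinear in this design"
        )


def _single_level_components(model: ModelSpec, design: StudyDesign) -> list[str]:
    single = set(design.single_level_facets)
    return [
        c
        for c in model.facet_components
        if component_facets(c) & single
    ]


def _require_compatible(model: ModelSpec, design: StudyDesign) -> None:
    bad = _single_level_components(model, design)
    if bad:
        raise ValueError(
            f"component(s) {bad} involve single-level facet(s) "
            f"{list(design.single_level_facets)}; their variance is structurally "
            "absent — drop them (backward_simplify does this automatically)"
        )


def anova_ems_estimate(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    model: ModelSpec | None = None,
) -> VarianceComponents:
    """Closed-form balanced-ANOVA variance components.

    Raises :class:`UnbalancedDataError` for unbalanced input (use
    :func:`reml_estimate` there) and :class:`NonIdentifiableError` when the
    requested components are aliased.
    """
    design = design or infer_design(records)
    model = model or ModelSpec.full(design)
    _require_compatible(model, design)
    y, facets = _data_array(records, design)
    strata = _anova_strata(y, facets)
    comps = model.facet_components
    C = _ems_matrix(strata, comps, design)
    _check_identifiable(C, comps + [RESIDUAL])
    ms = np.array([st.ms for st in strata])
    theta, *_ = np.linalg.lstsq(C, ms, rcond=None)
    clipped = frozenset(
        label for label, v in zip(comps + [RESIDUAL], theta) if v < 0
    )
    theta = np.clip(theta, 0.0, None)
    estimates = dict(zip(comps, theta[:-1].tolist()))
    estimates[RESIDUAL] = float(theta[-1])
    return VarianceComponents(
        estimates=estimates,
        grand_mean=float(y.mean()),
        method="anova_ems",
        converged=True,
        clipped=clipped,
        n_records=y.size,
        design=design,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_balanced(
    records: pd.DataFrame,
    design: StudyDesign,
    model: ModelSpec,
    tol: float,
    max_iter: int,
) -> VarianceComponents:
    y, facets = _data_array(records, design)
    N = y.size
    strata = _anova_strata(y, facets)
    comps = model.facet_components
    C = _ems_matrix(strata, comps, design)
    _check_identifiable(C, comps + [RESIDUAL])
    dfv = np.array([st.df for st in strata], dtype=float)
    ms = np.array([st.ms for st in strata])

    # start at the (clipped) ANOVA solution: on balanced data with an interior
    # optimum this is already the REML stationary point
    theta0, *_ = np.linalg.lstsq(C, ms, rcond=None)
    theta0 = np.clip(theta0, 0.0, None)
    if theta0.sum() <= 0:
        theta0[:] = max(float(np.var(y)), _LAM_FLOOR) / len(theta0)

    def negll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = np.maximum(C @ theta, _LAM_FLOOR)
        f = 0.5 * float(np.sum(dfv * (np.log(lam) + ms / lam)))
        g = 0.5 * (C.T @ (dfv * (1.0 / lam - ms / lam**2)))
        return f, g

    res = optimize.minimize(
        negll,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(theta0),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta = np.where(res.x < _BOUNDARY_TOL, 0.0, res.x)
    lam = np.maximum(C @ np.maximum(theta, 0.0), _LAM_FLOOR)
    loglik = -(
        0.5 * float(np.sum(dfv * (np.log(lam) + ms / lam)))
        + 0.5 * (N - 1) * math.log(2 * math.pi)
        + 0.5 * math.log(N)
    )
    info = 0.5 * (C.T * (dfv / lam**2)) @ C
    cov = pd.DataFrame(
        np.linalg.pinv(info), index=comps + [RESIDUAL], columns=comps + [RESIDUAL]
    )
    estimates = dict(zip(comps, theta[:-1].tolist()))
    estimates[RESIDUAL] = float(theta[-1])
    return VarianceComponents(
        estimates=estimates,
        grand_mean=float(y.mean()),
        method="reml",
        converged=bool(res.success),
        loglik=loglik,
        cov=cov,
        n_records=N,
        design=design,
    )


def _component_codes(
    records: pd.DataFrame, comps: Sequence[str]
) -> dict[str, np.ndarray]:
    facet_codes = {
        f: pd.Categorical(records[f]).codes.astype(np.int64) for f in FACET_ORDER
    }
    facet_sizes = {f: int(facet_codes[f].max()) + 1 for f in FACET_ORDER}
    out: dict[str, np.ndarray] = {}
    for label in comps:
        facets = [f for f in FACET_ORDER if f in component_facets(label)]
        code = np.zeros(len(records), dtype=np.int64)
        for f in facets:
            code = code * facet_sizes[f] + facet_codes[f]
        _, code = np.unique(code, return_inverse=True)
        out[label] = code
    return out


def _reml_dense(
    records: pd.DataFrame,
    design: StudyDesign,
    model: ModelSpec,
    tol: float,
    max_iter: int,
) -> VarianceComponents:
    """Dense-matrix REML for unbalanced tables (N capped at a few thousand)."""
    if records["muscle"].nunique() > 1:
        raise ValueError("multiple muscles in one table; fit each separately")
    N = len(records)
    if N > 4000:
        raise MemoryError(
            f"dense REML path is limited to 4000 records (got {N}); "
            "balanced tables of any size use the stratified path"
        )
    comps = model.facet_components
    # structural identifiability from the design-level EMS pattern
    pseudo = _pseudo_strata_check(design, comps)
    y = records["thickness_cm"].to_numpy(dtype=float)
    codes = _component_codes(records, comps)
    masks = {c: (codes[c][:, None] == codes[c][None, :]) for c in comps}

    theta0 = np.full(len(comps) + 1, max(float(np.var(y)), _LAM_FLOOR) / (len(comps) + 1))

    def build_V(theta: np.ndarray) -> np.ndarray:
        V = np.eye(N) * max(theta[-1], _LAM_FLOOR)
        for j, c in enumerate(comps):
            if theta[j] > 0:
                V += theta[j] * masks[c]
        return V

    X = np.ones((N, 1))

    def negll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        V = build_V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        logdetV = 2.0 * float(np.log(np.diag(L)).sum())
        Vinv = np.linalg.inv(V)
        XtVinvX = (X.T @ Vinv @ X).item()
        beta = ((X.T @ Vinv @ y) / XtVinvX).item()
        r = y - beta
        Vinv_r = Vinv @ r
        P = Vinv - (Vinv @ X) @ (Vinv @ X).T / XtVinvX
        f = 0.5 * (
            logdetV
            + math.log(XtVinvX)
            + (r @ Vinv_r).item()
            + (N - 1) * math.log(2 * math.pi)
        )
        Py = P @ y
        g = np.empty_like(theta)
        for j, c in enumerate(comps):
            code = codes[c]
            M = np.zeros((code.max() + 1, N))
            np.add.at(M, code, P)
            trPH = float(M[code, np.arange(N)].sum())
            s = np.bincount(code, weights=Py)
            g[j] = 0.5 * (trPH - float(s @ s))
        g[-1] = 0.5 * (float(np.trace(P)) - float(Py @ Py))
        return f, g

    res = optimize.minimize(
        negll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(theta0),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta = np.where(res.x < _BOUNDARY_TOL, 0.0, res.x)

    V = build_V(np.maximum(theta, _LAM_FLOOR * 0))
    Vinv = np.linalg.inv(V)
    XtVinvX = (X.T @ Vinv @ X).item()
    beta = ((X.T @ Vinv @ y) / XtVinvX).item()
    P = Vinv - (Vinv @ X) @ (Vinv @ X).T / XtVinvX
    # expected information: I_jk = 1/2 tr(P H_j P H_k)
    k = len(comps) + 1
    PH = []
    for c in comps:
        code = codes[c]
        M = np.zeros((N, code.max() + 1))
        np.add.at(M.T, code, P)  # M[:, g] accumulates columns of P by group
        PH.append((code, M))
    info = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            if a < len(comps) and b < len(comps):
                code_a, Ma = PH[a]
                code_b, Mb = PH[b]
                # tr(P Ha P Hb) = || Zb' P Za ||_F^2 with indicator Z's
                W = np.zeros((code_b.max() + 1, Ma.shape[1]))
                np.add.at(W, code_b, Ma)
                val = float((W**2).sum())
            elif a < len(comps):
                code_a, Ma = PH[a]
                val = float((Ma**2).sum())
            else:
                val = float((P**2).sum())
            info[a, b] = info[b, a] = 0.5 * val
    labels = comps + [RESIDUAL]
    cov = pd.DataFrame(np.linalg.pinv(info), index=labels, columns=labels)
    fval, _ = negll_grad(np.maximum(res.x, 0.0))
    estimates = dict(zip(comps, theta[:-1].tolist()))
    estimates[RESIDUAL] = float(theta[-1])
    return VarianceComponents(
        estimates=estimates,
        grand_mean=beta,
        method="reml",
        converged=bool(res.success),
        loglik=-fval,
        cov=cov,
        n_records=N,
        design=design,
    )


def _pseudo_strata_check(design: StudyDesign, comps: Sequence[str]) -> None:
    """Structural aliasing check from the design-level EMS pattern."""
    dummy = [
        _Stratum(facets=frozenset(sub), df=1, ms=0.0, n_levels=1)
        for k in range(1, len(design.multi_level_facets) + 1)
        for sub in combinations(design.multi_level_facets, k)
    ]
    if dummy:
        C = _ems_matrix(dummy, comps, design)
        _check_identifiable(C, list(comps) + [RESIDUAL])


def reml_estimate(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    model: ModelSpec | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    engine: Literal["auto", "balanced", "dense"] = "auto",
) -> VarianceComponents:
    """REML variance components with nonnegativity constraints.

    Requires >= 2 levels of the object facet and an identifiable model
    (components with identical expected-mean-square patterns raise
    :class:`NonIdentifiableError`).  Non-convergence within ``max_iter`` is
    reported through the ``converged`` flag, not an exception.
    """
    design = design or infer_design(records)
    model = model or ModelSpec.full(design)
    if design.levels[design.object_facet] < 2:
        raise ValueError("REML needs at least 2 levels of the object facet")
    _require_compatible(model, design)
    if engine == "balanced":
        return _reml_balanced(records, design, model, tol, max_iter)
    if engine == "dense":
        return _reml_dense(records, design, model, tol, max_iter)
    try:
        return _reml_balanced(records, design, model, tol, max_iter)
    except UnbalancedDataError:
        return _reml_dense(records, design, model, tol, max_iter)


def _fit(
    records: pd.DataFrame,
    design: StudyDesign,
    model: ModelSpec,
    method: str,
) -> VarianceComponents:
    if method == "anova_ems":
        return anova_ems_estimate(records, design, model)
    if method == "reml":
        return reml_estimate(records, design, model)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# backward simplification & model-consistency check
# ---------------------------------------------------------------------------


@dataclass
class DropEvent:
    component: str
    reason: str
    estimate: float | None = None

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "reason": self.reason,
            "estimate": self.estimate,
        }


def backward_simplify(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    full_model: ModelSpec | None = None,
    drop_tol: float = 1e-6,
    protected: Iterable[str] | None = None,
    method: str = "reml",
    criterion: Literal["estimate", "lrt"] = "estimate",
    lrt_cutoff: float = 3.84,
) -> tuple[ModelSpec, VarianceComponents, list[DropEvent]]:
    """Iteratively remove components that contribute no meaningful variance.

    Removal order and rules (deterministic; ties broken lexicographically):

    1. components on single-level facets (structurally absent variance);
    2. components aliased with another component or the residual
       (non-identifiable), non-protected ones first;
    3. refitting after each drop, the non-protected component with the
       smallest estimate when it falls below ``drop_tol`` (cm^2);
    4. with ``criterion='lrt'`` additionally: the component whose removal
       changes the restricted log-likelihood the least, when twice that change
       is below ``lrt_cutoff`` (default 3.84, the 5% chi-square(1) point).

    The estimate threshold alone (rule 3) only removes components whose REML
    solution sits exactly on the zero boundary; the likelihood-ratio rule
    reproduces the analyst decision of excluding whole blocks of negligible
    interactions.
    """
    design = design or infer_design(records)
    model = full_model or ModelSpec.full(design, include_aliased=False)
    if protected is not None:
        model = ModelSpec(model.components, frozenset(protected) | {RESIDUAL})
    log: list[DropEvent] = []

    for label in sorted(_single_level_components(model, design)):
        if label in model.protected:
            raise NonIdentifiableError(
                f"protected component {label!r} involves a single-level facet; "
                "its variance is structurally absent (design flaw)"
            )
        model = model.drop(label)
        log.append(DropEvent(label, "structurally absent (single-level facet)"))

    # aliasing: remove non-protected members of confounded pairs
    while True:
        try:
            _pseudo_strata_check(design, model.facet_components)
            break
        except NonIdentifiableError as exc:
            pair = list(exc.pair or ())
            droppable = sorted(
                c for c in pair if c not in model.protected and c != RESIDUAL
            )
            if not droppable:
                raise
            victim = max(droppable, key=lambda c: (component_order(c), c))
            model = model.drop(victim)
            log.append(DropEvent(victim, "aliased (non-identifiable)"))

    fit = _fit(records, design, model, method)
    while True:
        candidates = sorted(
            c for c in model.facet_components if c not in model.protected
        )
        if not candidates:
            break
        below = [c for c in candidates if fit.get(c) < drop_tol]
        if below:
            victim = min(below, key=lambda c: (fit.get(c), c))
            model = model.drop(victim)
            log.append(
                DropEvent(victim, f"estimate below drop_tol={drop_tol:g}", fit.get(victim))
            )
            fit = _fit(records, design, model, method)
            continue
        if criterion == "lrt" and method == "reml" and fit.loglik is not None:
            best: tuple[float, str, VarianceComponents] | None = None
            for c in candidates:
                reduced = _fit(records, design, model.drop(c), method)
                stat = 2.0 * (fit.loglik - (reduced.loglik or -np.inf))
                if best is None or (stat, c) < (best[0], best[1]):
                    best = (stat, c, reduced)
            if best is not None and best[0] < lrt_cutoff:
                stat, victim, reduced = best
                model = model.drop(victim)
                log.append(
                    DropEvent(
                        victim,
                        f"negligible likelihood contribution (2*dLL={stat:.3g} "
                        f"< {lrt_cutoff:g})",
                        fit.get(victim),
                    )
                )
                fit = reduced
                continue
        break
    return model, fit, log


def model_ladder(
    design: StudyDesign, orders: Sequence[int] = (1, 2, 3)
) -> dict[str, ModelSpec]:
    """Nested models with interactions up to the given orders."""
    names = {1: "one-way", 2: "two-way", 3: "three-way", 4: "four-way"}
    return {
        names.get(k, f"order-{k}"): ModelSpec.full(design, max_order=k)
        for k in orders
    }


@dataclass
class ConsistencyReport:
    """SEM agreement across a ladder of nested models."""

    sems: dict[str, float | None]
    errors: dict[str, str]
    max_rel_diff: float | None
    threshold: float
    passed: bool | None

    def to_dict(self) -> dict:
        return {
            "sems": self.sems,
            "errors": self.errors,
            "max_rel_diff": self.max_rel_diff,
            "threshold": self.threshold,
            "passed": self.passed,
        }


def model_consistency_check(
    records: pd.DataFrame,
    design: StudyDesign | None = None,
    ladder: dict[str, ModelSpec] | Sequence[ModelSpec] | None = None,
    mode: str = "intra",
    threshold: float = 0.05,
    method: str = "reml",
) -> ConsistencyReport:
    """Fit each rung of a nested model ladder and compare SEMs.

    Error-variance totals — hence SEMs — are invariant to how balanced data
    are partitioned across nested models, so materially different SEMs flag an
    ineligible (mis-specified) model.  A failed rung is reported, not raised.
    """
    from .reliability import sem  # local import to avoid a cycle

    design = design or infer_design(records)
    if ladder is None:
        ladder = model_ladder(design)
    if not isinstance(ladder, dict):
        ladder = {f"model_{i + 1}": m for i, m in enumerate(ladder)}
    sems: dict[str, float | None] = {}
    errors: dict[str, str] = {}
    for name, spec in ladder.items():
        try:
            usable = ModelSpec(
                frozenset(
                    c
                    for c in spec.components
                    if c == RESIDUAL
                    or not (component_facets(c) & set(design.single_level_facets))
                ),
                spec.protected,
            )
            fit = _fit(records, design, usable, method)
            sems[name] = sem(fit, mode)
        except Exception as exc:  # noqa: BLE001 - report, don't abort the ladder
            sems[name] = None
            errors[name] = str(exc)
    values = [v for v in sems.values() if v is not None]
    if len(values) < 2:
        return ConsistencyReport(sems, errors, None, threshold, None)
    ref = float(np.mean(values))
    max_rel = max(abs(v - ref) / ref for v in values) if ref > 0 else 0.0
    return ConsistencyReport(sems, errors, max_rel, threshold, max_rel <= threshold)
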