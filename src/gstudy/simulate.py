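"""Synthetic measurement tables from the crossed random-effects model.

The generator inverts the model the estimators assume: a thickness value for
cell (participant p, repetition r, occasion o, observer ob) is

    y = mu + sum_c u_c + e,

where each variance component c (a nonempty subset of the facets) contributes
one zero-mean Gaussian effect u_c ~ N(0, sigma2_c) drawn once per distinct
level combination of its facets, and e ~ N(0, sigma2_res) is drawn per record.
Gaussian effects are used because the variance-component model constrains only
second moments and Gaussianity makes REML the true maximum-likelihood family.

Presets emulate the two ultrasound study arms: the able-bodied (AB) design
(30 participants x 3 observers x 2 occasions x 3 repetitions per muscle) and
the spinal-cord-injury (SCI) design (30 participants x 1 observer x 1 occasion
x 3 repetitions), with participant-level variances taken from the reported
per-muscle variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    FACET_ORDER,
    RESIDUAL,
    StudyDesign,
    component_facets,
    sort_components,
)


class SpecError(ValueError):
    """Invalid simulation specification."""


def _level_labels(facet: str, n: int) -> list[str]:
    prefix = {
        "participant": "P",
        "observer": "Obs",
        "occasion": "Occ",
        "repetition": "Rep",
    }[facet]
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class SimulationSpec:
    """Generating model for one muscle: grand mean, variances, design, seed."""

    grand_mean_cm: float
    variance_map: dict[str, float]
    design: StudyDesign
    seed: int | None = None
    muscle: str = "muscle"

    def __post_init__(self) -> None:
        vm = dict(self.variance_map)
        vm.setdefault(RESIDUAL, 0.0)
        for label, var in vm.items():
            if not np.isfinite(var) or var < 0:
                raise SpecError(f"variance for {label!r} must be >= 0, got {var!r}")
            if label != RESIDUAL:
                facets = component_facets(label)
                absent = facets - set(self.design.facets)
                if absent:
                    raise SpecError(
                        f"component {label!r} references facet(s) {sorted(absent)} "
                        "not present in the design"
                    )
        self.variance_map = vm

    @property
    def total_variance(self) -> float:
        """Sum of generating variances over components that actually vary.

        Components touching a single-level facet are structurally confounded
        with the grand mean and contribute no draw.
        """
        total = self.variance_map[RESIDUAL]
        single = set(self.design.single_level_facets)
        for label, var in self.variance_map.items():
            if label == RESIDUAL:
                continue
            if component_facets(label) & single:
                continue
            total += var
        return total


def simulate_study(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one full-cross measurement table from the generating model.

    Reproducible given ``spec.seed``; effects are drawn in a fixed component
    order.  Values are *not* truncated at zero — a warning is emitted if any
    simulated thickness is non-positive (with realistic means and variances
    this is vanishingly rare, and truncation would bias the components).
    """
    design = spec.design
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    facets = [f for f in FACET_ORDER if f in design.facets]
    dims = [design.levels[f] for f in facets]
    axis_of = {f: i for i, f in enumerate(facets)}
    single = set(design.single_level_facets)

    y = np.full(dims, float(spec.grand_mean_cm))
    labels = [c for c in sort_components(spec.variance_map) if c != RESIDUAL]
    for label in labels:
        var = spec.variance_map[label]
        comp_facets = component_facets(label)
        if var == 0 or comp_facets & single:
            continue  # single-level facets contribute no draw
        shape = [
            dims[i] if facets[i] in comp_facets else 1 for i in range(len(facets))
        ]
        y = y + rng.normal(0.0, np.sqrt(var), size=shape)
    res_var = spec.variance_map[RESIDUAL]
    if res_var > 0:
        y = y + rng.normal(0.0, np.sqrt(res_var), size=dims)
    else:
        y = np.broadcast_to(y, dims).copy()

    if np.any(y <= 0):
        warnings.warn(
            f"{int(np.sum(y <= 0))} simulated thickness value(s) <= 0 cm; "
            "values are not truncated",
            stacklevel=2,
        )

    index = pd.MultiIndex.from_product(
        [_level_labels(f, design.levels[f]) for f in facets], names=facets
    )
    out = pd.DataFrame(index=index).reset_index()
    for f in FACET_ORDER:
        if f not in out.columns:  # facet absent from the design: one level
            out[f] = _level_labels(f, 1)[0]
    out["muscle"] = spec.muscle
    out["thickness_cm"] = y.reshape(-1)
    return out[list(FACET_ORDER) + ["muscle", "thickness_cm"]].copy()


def _ab_design(n_participants: int = 30) -> StudyDesign:
    return StudyDesign(
        facets=FACET_ORDER,
        levels={
            "participant": n_participants,
            "observer": 3,
            "occasion": 2,
            "repetition": 3,
        },
    )


def _sci_design(n_participants: int = 30) -> StudyDesign:
    return StudyDesign(
        facets=FACET_ORDER,
        levels={
            "participant": n_participants,
            "observer": 1,
            "occasion": 1,
            "repetition": 3,
        },
    )


# Participant-level variances are the reported per-muscle values (Gmax 0.4396,
# Gmed 0.1378 with p x ob 0.0865, Gmin 0.0313 with p x o x ob 0.0082); the
# remaining components are package defaults chosen to match the printed
# per-muscle SEM/G magnitudes (see docs/methods.md).  All repetition-related
# variances default to 0: repetitions within an occasion showed no systematic
# variance in the source study.
_PRESETS: dict[str, dict] = {
    "ab_gmax": dict(
        grand_mean_cm=3.85,
        variance_map={
            "p": 0.4396,
            "o": 0.005,
            "po": 0.020,
            "ob": 0.010,
            "pob": 0.020,
            RESIDUAL: 0.120,
        },
        design="ab",
        muscle="Gmax",
    ),
    "ab_gmed": dict(
        grand_mean_cm=2.31,
        variance_map={
            "p": 0.1378,
            "o": 0.003,
            "po": 0.015,
            "ob": 0.005,
            "pob": 0.0865,
            RESIDUAL: 0.055,
        },
        design="ab",
        muscle="Gmed",
    ),
    "ab_gmin": dict(
        grand_mean_cm=1.19,
        variance_map={
            "p": 0.0313,
            "o": 0.0005,
            "po": 0.001,
            "ob": 0.0005,
            "pob": 0.0015,
            "poob": 0.0082,
            RESIDUAL: 0.009,
        },
        design="ab",
        muscle="Gmin",
    ),
    "sci_default": dict(
        grand_mean_cm=1.83,
        variance_map={"p": 0.30, "r": 0.0, RESIDUAL: 0.005},
        design="sci",
        muscle="Gmed",
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset_spec(
    name: str, seed: int | None = None, n_participants: int | None = None
) -> SimulationSpec:
    """A ready-made :class:`SimulationSpec` for one of the study arms."""
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise SpecError(
            f"unknown preset {name!r}; available presets: {preset_names()}"
        ) from None
    if cfg["design"] == "ab":
        design = _ab_design(n_participants or 30)
    else:
        design = _sci_design(n_participants or 30)
    return SimulationSpec(
        grand_mean_cm=cfg["grand_mean_cm"],
        variance_map=dict(cfg["variance_map"]),
        design=design,
        seed=seed,
        muscle=cfg["muscle"],
    )


def spec_from_config(cfg: dict, seed: int | None = None) -> SimulationSpec:
    """Build a spec from a plain dict (YAML/JSON config)."""
    design = StudyDesign(
        facets=tuple(cfg.get("facets", FACET_ORDER)),
        levels={k: int(v) for k, v in cfg["levels"].items()},
    )
    return SimulationSpec(
        grand_mean_cm=float(cfg["grand_mean_cm"]),
        variance_map={k: float(v) for k, v in cfg["variance_map"].items()},
        design=design,
        seed=cfg.get("seed", seed),
        muscle=cfg.get("muscle", "muscle"),
    )
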