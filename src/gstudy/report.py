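"""Run configuration, descriptive statistics and pipeline orchestration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman
from .design import infer_design, load_measurements
from .reliability import reliability_table, results_to_frame
from .varcomp import backward_simplify

logger = logging.getLogger("gstudy")


@dataclass
class RunConfig:
    """Effective configuration of one analysis run (serialised for provenance)."""

    input_path: str | None = None
    preset: str | None = None
    muscles: Sequence[str] | None = None
    modes: Sequence[str] = ("intra",)
    method: str = "reml"
    criterion: str = "lrt"
    drop_tol: float = 1e-6
    protected: Sequence[str] | None = None
    ci_method: str = "wald_delta"
    ci_level: float = 0.95
    seed: int | None = None
    out_dir: str = "."
    agreement: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.input_path is None and self.preset is None:
            raise ValueError("either input_path or preset must be given")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-muscle mean, SD (n-1), median and quartiles (linear interpolation).

    A single observation yields SD 0 with ``sd_defined=False``.
    """
    rows = []
    for muscle, sub in records.groupby("muscle", sort=True):
        y = sub["thickness_cm"].to_numpy(dtype=float)
        rows.append(
            {
                "muscle": muscle,
                "n": len(y),
                "mean": float(y.mean()),
                "sd": float(y.std(ddof=1)) if len(y) > 1 else 0.0,
                "sd_defined": len(y) > 1,
                "median": float(np.median(y)),
                "q1": float(np.percentile(y, 25)),
                "q3": float(np.percentile(y, 75)),
            }
        )
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline and write machine-readable outputs.

    Writes per-run: ``components.json`` (per-muscle variance components and
    drop logs), ``reliability_<mode>.csv``, ``agreement.json``, ``run.log``
    and ``config.json``.  Deterministic for a given config + seed.  Returns a
    mapping of output names to paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, str] = {"log": str(log_path)}
    try:
        if config.input_path:
            records, design = load_measurements(config.input_path)
        else:
            from .simulate import preset_spec, simulate_study

            spec = preset_spec(config.preset, seed=config.seed)
            records = simulate_study(spec)
            design = infer_design(records)
        if config.muscles:
            records = records[records["muscle"].isin([str(m) for m in config.muscles])]
            if len(records) == 0:
                raise ValueError(f"no records for muscles {list(config.muscles)}")
            design = infer_design(records)
        logger.info("design: %s", design.to_dict())

        comp_out: dict[str, dict] = {}
        for muscle, sub in records.groupby("muscle", sort=True):
            try:
                model, comps, log = backward_simplify(
                    sub,
                    infer_design(sub),
                    drop_tol=config.drop_tol,
                    protected=config.protected,
                    method=config.method,
                    criterion=config.criterion,  # type: ignore[arg-type]
                )
                comp_out[str(muscle)] = {
                    "components": comps.to_dict(),
                    "dropped": [ev.to_dict() for ev in log],
                }
                for ev in log:
                    logger.info("%s: dropped %s (%s)", muscle, ev.component, ev.reason)
                if comps.clipped:
                    logger.info("%s: clipped to 0: %s", muscle, sorted(comps.clipped))
                if not comps.converged:
                    logger.warning("%s: fit did not converge", muscle)
            except Exception as exc:  # noqa: BLE001
                comp_out[str(muscle)] = {"error": str(exc)}
                logger.error("%s: %s", muscle, exc)
        comp_path = out_dir / "components.json"
        comp_path.write_text(
            json.dumps({"config": config.to_dict(), "muscles": comp_out}, indent=2)
        )
        outputs["components"] = str(comp_path)

        desc = descriptive_stats(records)
        desc_path = out_dir / "descriptives.csv"
        desc.to_csv(desc_path, index=False)
        outputs["descriptives"] = str(desc_path)

        for mode in config.modes:
            results, errors = reliability_table(
                records,
                mode=mode,  # type: ignore[arg-type]
                method=config.method,
                criterion=config.criterion,
                drop_tol=config.drop_tol,
                protected=config.protected,
                ci_method=config.ci_method,
                level=config.ci_level,
                seed=config.seed,
            )
            frame = results_to_frame(results)
            for muscle, msg in errors.items():
                logger.error("%s (%s): %s", muscle, mode, msg)
                frame = pd.concat(
                    [frame, pd.DataFrame([{"muscle": muscle, "mode": mode, "band": f"ERROR: {msg}"}])],
                    ignore_index=True,
                )
            path = out_dir / f"reliability_{mode}.csv"
            frame.to_csv(path, index=False)
            outputs[f"reliability_{mode}"] = str(path)

        if config.agreement:
            ba_out: dict[str, dict] = {}
            for muscle, sub in records.groupby("muscle", sort=True):
                try:
                    ba = bland_altman(sub)
                    ba_out[str(muscle)] = ba.to_dict()
                except Exception as exc:  # noqa: BLE001
                    ba_out[str(muscle)] = {"error": str(exc)}
                    logger.error("%s (agreement): %s", muscle, exc)
            ba_path = out_dir / "agreement.json"
            ba_path.write_text(json.dumps(ba_out, indent=2))
            outputs["agreement"] = str(ba_path)

        cfg_path = out_dir / "config.json"
        cfg_path.write_text(json.dumps(config.to_dict(), indent=2))
        outputs["config"] = str(cfg_path)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
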