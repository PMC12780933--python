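import numpy as np
import pandas as pd
import pytest

from gstudy.design import FACET_ORDER, StudyDesign
from gstudy.simulate import SimulationSpec, preset_spec, simulate_study


def make_table(values: dict[tuple, float], muscle: str = "M") -> pd.DataFrame:
    """Build a long table from {(participant, observer, occasion, repetition): y}."""
    rows = []
    for (p, ob, o, r), y in values.items():
        rows.append(
            {
                "participant": str(p),
                "observer": str(ob),
                "occasion": str(o),
                "repetition": str(r),
                "muscle": muscle,
                "thickness_cm": float(y),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_2x2() -> pd.DataFrame:
    """2 participants x 2 observers, one record each: values 1, 2, 3, 4."""
    return make_table(
        {
            ("A", "1", "1", "1"): 1.0,
            ("A", "2", "1", "1"): 2.0,
            ("B", "1", "1", "1"): 3.0,
            ("B", "2", "1", "1"): 4.0,
        }
    )


@pytest.fixture
def sci_table() -> pd.DataFrame:
    """One draw from the single-observer, single-occasion study arm."""
    return simulate_study(preset_spec("sci_default", seed=202))


@pytest.fixture
def ab_table() -> pd.DataFrame:
    """One draw from the three-observer, two-occasion study arm."""
    return simulate_study(preset_spec("ab_gmax", seed=303))


def crossed_design(n_p: int, n_ob: int = 1, n_o: int = 1, n_r: int = 1) -> StudyDesign:
    return StudyDesign(
        facets=FACET_ORDER,
        levels={
            "participant": n_p,
            "observer": n_ob,
            "occasion": n_o,
            "repetition": n_r,
        },
    )
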