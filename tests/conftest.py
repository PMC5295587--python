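import pandas as pd
import pytest

from dfscreen.panel import ChromosomeArm, Deficiency, DeficiencyPanel
from dfscreen.viability import HISet


@pytest.fixture
def toy_panel() -> DeficiencyPanel:
    """Two short arms, four deficiencies, with a euchromatin table."""
    arms = (ChromosomeArm("X", 1000), ChromosomeArm("2L", 1000))
    defs = (
        Deficiency("DfX-1", "X", 0, 300),
        Deficiency("DfX-2", "X", 250, 600),
        Deficiency("Df2L-1", "2L", 100, 400),
        Deficiency("Df2L-2", "2L", 500, 900),
    )
    euch = {"X": ((0, 1000),), "2L": ((0, 1000),)}
    return DeficiencyPanel(arms=arms, deficiencies=defs, euchromatin=euch)


def make_hi_set(intervals, species="san", temperature="18") -> HISet:
    """Build an HI set from (arm, start, end) triples with generated ids."""
    ivs = {f"Df-{i}": iv for i, iv in enumerate(intervals)}
    return HISet(species, temperature, frozenset(ivs), ivs)


@pytest.fixture
def counts_equal() -> pd.DataFrame:
    """Counts with no dearth anywhere: two stocks x 2 species x 2 temps."""
    rows = []
    for stock in ("DfX-1", "DfX-2"):
        for sp in ("san", "sim"):
            for temp in ("18", "24"):
                for vial in (1, 2):
                    rows.append(
                        {
                            "stock_id": stock,
                            "species": sp,
                            "temperature": temp,
                            "vial_id": vial,
                            "n_bal": 50,
                            "n_df": 50,
                        }
                    )
    return pd.DataFrame(rows)
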