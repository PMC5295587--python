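"""Synthetic deficiency-screen generator.

Emulates the data-generating process the downstream analysis assumes: a
panel of ~223 deletion stocks tiling five chromosome arms, crossed as two
hybrid genotypes (mel/san and mel/sim) at two temperatures (18 and 24
degrees), with latent hybrid-incompatibility (HI) loci whose lethality
penetrance may depend on species and temperature, and vial-level count
noise.

Count model
-----------
Per stock x species x temperature x vial, the two scored progeny classes
are independent Poisson draws:

    n_bal ~ Poisson(lam)
    n_df  ~ Poisson(lam * v),   v = prod over covered loci of (1 - penetrance)

so the balancer class is the unaffected 1:1 control and the deficiency
class is thinned by the joint survival ``v`` of every HI locus the deletion
uncovers.  A vial fails to produce progeny (both counts zero) with a fixed
probability, emulating the empirical observation that roughly half of
replicate vials yield offspring.  All randomness flows from one seeded
generator in documented order, so a scenario is reproducible bit-for-bit
from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ChromosomeArm, DEFAULT_ARMS, Deficiency, DeficiencyPanel

__all__ = [
    "HILocus",
    "ScreenScenario",
    "SPECIES",
    "TEMPERATURES",
    "generate_panel",
    "plant_loci",
    "simulate_screen",
    "preset_scenario",
    "write_counts",
    "read_counts",
    "write_truth",
    "COUNT_COLUMNS",
]

SPECIES: tuple[str, str] = ("san", "sim")
TEMPERATURES: tuple[str, str] = ("18", "24")

COUNT_COLUMNS = ["stock_id", "species", "temperature", "vial_id", "n_bal", "n_df"]


@dataclass(frozen=True)
class HILocus:
    """A latent recessive HI allele at a point position on an arm.

    ``penetrance`` maps (species, temperature) to the probability that a
    deficiency-class hybrid uncovering this locus dies.
    """

    arm: str
    position: int
    penetrance: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("locus position must be >= 0")
        for cond, p in self.penetrance.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance {p} for {cond} outside [0, 1]")

    def pen(self, species: str, temperature: str) -> float:
        return float(self.penetrance.get((species, temperature), 0.0))


@dataclass(frozen=True)
class ScreenScenario:
    """Parameters of one synthetic screen.

    Defaults mirror the study scale: 223 deficiencies over the five major
    arms, two hybrid genotypes at two temperatures, at least 20 replicate
    vials per cross with about half producing progeny.
    """

    n_deficiencies: int = 223
    arms: tuple[ChromosomeArm, ...] = DEFAULT_ARMS
    overlap_fraction: float = 0.15   # shared fraction between tiling neighbours
    length_jitter: float = 0.10      # +/- relative jitter on interval lengths
    loci: tuple[HILocus, ...] = ()
    mean_progeny_per_class: float = 12.0  # Poisson lambda per productive vial
    vials_per_cross: int = 20
    vial_failure_prob: float = 0.5   # P(vial yields no progeny at all)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.mean_progeny_per_class <= 0:
            raise ValueError("mean_progeny_per_class must be > 0")
        if self.vials_per_cross < 1:
            raise ValueError("vials_per_cross must be >= 1")
        if not 0.0 <= self.overlap_fraction:
            raise ValueError("overlap_fraction must be >= 0")
        if not 0.0 <= self.vial_failure_prob < 1.0:
            raise ValueError("vial_failure_prob must be in [0, 1)")


def _arm_allocation(scenario: ScreenScenario) -> list[int]:
    """Deficiencies per arm, proportional to arm length (largest remainder)."""
    lengths = np.array([a.length for a in scenario.arms], dtype=float)
    raw = scenario.n_deficiencies * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    remainder = scenario.n_deficiencies - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def generate_panel(scenario: ScreenScenario) -> DeficiencyPanel:
    """Generate a deficiency panel tiling the scenario's arms.

    Neighbouring deficiencies on an arm share ``overlap_fraction`` of a
    tile, so that overlapping deletions are informative downstream; with
    ``overlap_fraction == 0`` intervals are pairwise disjoint.  Deterministic
    given the scenario seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    defs: list[Deficiency] = []
    for arm, n_arm in zip(scenario.arms, _arm_allocation(scenario)):
        if n_arm == 0:
            continue
        step = arm.length / n_arm
        max_len = step * (1.0 + scenario.overlap_fraction)
        if max_len > arm.length:
            raise ValueError(
                f"infeasible tiling on arm {arm.name}: interval length "
                f"{max_len:.0f} exceeds arm length {arm.length}"
            )
        jitter = rng.uniform(
            1.0 - scenario.length_jitter, 1.0 + scenario.length_jitter, size=n_arm
        )
        for i in range(n_arm):
            start = int(round(i * step))
            length = int(round(min(max_len, step * (1.0 + scenario.overlap_fraction) * jitter[i])))
            length = max(length, 1)
            end = min(start + length, arm.length)
            stock_id = f"Df{arm.name}-{i + 1:03d}"
            defs.append(Deficiency(stock_id, arm.name, start, end))
    return DeficiencyPanel(arms=scenario.arms, deficiencies=tuple(defs))


def _covered_loci(d: Deficiency, loci: Sequence[HILocus]) -> list[HILocus]:
    return [
        loc
        for loc in loci
        if loc.arm == d.arm and d.start <= loc.position < d.end
    ]


def survival(
    d: Deficiency, loci: Sequence[HILocus], species: str, temperature: str
) -> float:
    """Joint survival of the deficiency class: product of (1 - penetrance)."""
    v = 1.0
    for loc in _covered_loci(d, loci):
        v *= 1.0 - loc.pen(species, temperature)
    return v


def simulate_screen(
    panel: DeficiencyPanel,
    scenario: ScreenScenario,
    species: Sequence[str] = SPECIES,
    temperatures: Sequence[str] = TEMPERATURES,
) -> pd.DataFrame:
    """Simulate vial-level progeny counts for every stock x condition.

    Returns a DataFrame with columns ``stock_id, species, temperature,
    vial_id, n_bal, n_df``, one row per vial; failed vials carry zero in
    both classes.  Deterministic given the scenario seed.
    """
    arm_lengths = {a.name: a.length for a in panel.arms}
    for loc in scenario.loci:
        if loc.arm not in arm_lengths:
            raise ValueError(f"locus on unknown arm {loc.arm!r}")
        if loc.position >= arm_lengths[loc.arm]:
            raise ValueError(f"locus position {loc.position} off arm {loc.arm}")

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    lam = scenario.mean_progeny_per_class
    n_vials = scenario.vials_per_cross

    # Survival multipliers in a fixed stock-major order.
    rows_stock, rows_sp, rows_temp, v_list = [], [], [], []
    for d in panel.deficiencies:
        for sp in species:
            for temp in temperatures:
                rows_stock.append(d.stock_id)
                rows_sp.append(sp)
                rows_temp.append(temp)
                v_list.append(survival(d, scenario.loci, sp, temp))

    n_groups = len(rows_stock)
    v_arr = np.asarray(v_list)
    # Draw order: vial failures, then balancer counts, then deficiency counts.
    ok = rng.random((n_groups, n_vials)) >= scenario.vial_failure_prob
    n_bal = rng.poisson(lam, size=(n_groups, n_vials))
    n_df = rng.poisson(lam * v_arr[:, None], size=(n_groups, n_vials))
    n_bal = np.where(ok, n_bal, 0)
    n_df = np.where(ok, n_df, 0)

    frame = pd.DataFrame(
        {
            "stock_id": np.repeat(rows_stock, n_vials),
            "species": np.repeat(rows_sp, n_vials),
            "temperature": np.repeat(rows_temp, n_vials),
            "vial_id": np.tile(np.arange(1, n_vials + 1), n_groups),
            "n_bal": n_bal.ravel(),
            "n_df": n_df.ravel(),
        }
    )
    return frame


def plant_loci(
    scenario: ScreenScenario,
    n_loci: int,
    target_species: str,
    temp_specific_fraction: float,
    base_penetrance: tuple[float, float] = (0.5, 1.0),
    restricted_temperature: str | None = None,
) -> tuple[HILocus, ...]:
    """Draw HI loci at random positions with the given penetrance structure.

    A fraction ``temp_specific_fraction`` of loci is penetrant at a single
    temperature only (``restricted_temperature`` if given, else alternating);
    the rest are equally penetrant at both temperatures.  Loci affect only
    ``target_species``; penetrance for the other species is zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    lengths = np.array([a.length for a in scenario.arms], dtype=float)
    arm_probs = lengths / lengths.sum()
    loci = []
    for i in range(n_loci):
        arm = scenario.arms[rng.choice(len(scenario.arms), p=arm_probs)]
        position = int(rng.integers(0, arm.length))
        p = float(rng.uniform(*base_penetrance))
        temp_specific = rng.random() < temp_specific_fraction
        if temp_specific:
            p = max(p, 0.8)  # restricted loci are strongly penetrant when active
            if restricted_temperature is not None:
                active = restricted_temperature
            else:
                active = TEMPERATURES[i % 2]
            pen = {
                (target_species, active): p,
                (target_species, TEMPERATURES[1 - TEMPERATURES.index(active)]): 0.0,
            }
        else:
            pen = {(target_species, t): p for t in TEMPERATURES}
        loci.append(HILocus(arm.name, position, pen))
    return tuple(loci)


_PRESETS = ("san_like", "sim_like")


def preset_scenario(name: str, seed: int = 0) -> ScreenScenario:
    """Packaged scenarios mirroring the two hybrid crosses.

    ``san_like``: many HI loci (70) in the san genome, penetrance mostly
    shared between 18 and 24 degrees — the cross where most incompatibilities
    act at both temperatures.  ``sim_like``: few loci (15) in the sim genome,
    mostly penetrant at 24 degrees only — the cross where incompatibility is
    strongly temperature-dependent.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")
    base = ScreenScenario(seed=seed, name=name)
    if name == "san_like":
        loci = plant_loci(
            base, n_loci=70, target_species="san", temp_specific_fraction=0.15
        )
    else:
        loci = plant_loci(
            base,
            n_loci=15,
            target_species="sim",
            temp_specific_fraction=0.9,
            base_penetrance=(0.8, 1.0),
            restricted_temperature="24",
        )
    return replace(base, loci=loci)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(
        path,
        sep="\t",
        dtype={"stock_id": str, "species": str, "temperature": str, "vial_id": str},
    )
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts file {path}: missing columns {missing}")
    if (counts["n_bal"] < 0).any() or (counts["n_df"] < 0).any():
        raise ValueError(f"counts file {path}: negative counts")
    return counts[COUNT_COLUMNS]


def write_truth(loci: Sequence[HILocus], path: str | Path) -> None:
    """Write the planted-loci truth table used by recovery tests."""
    with open(path, "w") as fh:
        fh.write("arm\tposition\tpen_san_18\tpen_san_24\tpen_sim_18\tpen_sim_24\n")
        for loc in loci:
            fh.write(
                f"{loc.arm}\t{loc.position}\t"
                f"{loc.pen('san', '18')}\t{loc.pen('san', '24')}\t"
                f"{loc.pen('sim', '18')}\t{loc.pen('sim', '24')}\n"
            )
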