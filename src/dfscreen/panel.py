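"""Deficiency panel representation and interval arithmetic.

A deficiency screen tiles a genome with deletion-bearing stocks.  Each
deficiency is a half-open interval ``[start, end)`` on a chromosome arm,
identified by a unique stock id.  Coordinates are 0-based integers in
abstract units; the panel file must already carry numeric coordinates
(cytological band definitions are out of scope).

The default arm set is the five major Drosophila arms (X, 2L, 2R, 3L, 3R);
arms map onto chromosomes by stripping the L/R suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ChromosomeArm",
    "Deficiency",
    "DeficiencyPanel",
    "PanelValidationError",
    "DEFAULT_ARMS",
    "parse_panel",
    "parse_euchromatin",
    "intervals_overlap",
    "coverage_fraction",
    "interval_union_length",
    "arm_to_chromosome",
]


class PanelValidationError(ValueError):
    """Raised when a panel, arm or euchromatin table fails validation."""


def arm_to_chromosome(arm: str) -> str:
    """Collapse an arm label to its chromosome label (2L, 2R -> 2; X -> X)."""
    if arm.upper().endswith(("L", "R")) and len(arm) > 1:
        return arm[:-1]
    return arm


@dataclass(frozen=True)
class ChromosomeArm:
    """A chromosome arm with a coordinate length.

    Parameters
    ----------
    name
        Arm label, e.g. ``"2L"``.
    length
        Arm length in coordinate units; must be positive.
    chromosome
        Chromosome label the arm belongs to.  Derived from ``name`` when
        omitted (``2L``/``2R`` -> ``2``, ``X`` -> ``X``).
    """

    name: str
    length: int
    chromosome: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise PanelValidationError(f"arm {self.name!r}: length must be > 0")
        if not self.chromosome:
            object.__setattr__(self, "chromosome", arm_to_chromosome(self.name))


# Approximate euchromatic extents of the five major D. melanogaster arms,
# in base pairs; used as the default synthetic genome.
DEFAULT_ARMS: tuple[ChromosomeArm, ...] = (
    ChromosomeArm("X", 23_500_000),
    ChromosomeArm("2L", 23_500_000),
    ChromosomeArm("2R", 25_300_000),
    ChromosomeArm("3L", 28_100_000),
    ChromosomeArm("3R", 32_100_000),
)


@dataclass(frozen=True)
class Deficiency:
    """A deletion interval ``[start, end)`` on an arm, tagged by stock id."""

    stock_id: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise PanelValidationError(
                f"deficiency {self.stock_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DeficiencyPanel:
    """A validated collection of deficiencies on a set of arms."""

    arms: tuple[ChromosomeArm, ...]
    deficiencies: tuple[Deficiency, ...]
    euchromatin: Mapping[str, tuple[tuple[int, int], ...]] | None = None
    _by_arm: dict[str, ChromosomeArm] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_arm = {a.name: a for a in self.arms}
        if len(self._by_arm) != len(self.arms):
            raise PanelValidationError("duplicate arm names")
        seen: set[str] = set()
        for d in self.deficiencies:
            if d.stock_id in seen:
                raise PanelValidationError(f"duplicate stock_id {d.stock_id!r}")
            seen.add(d.stock_id)
            arm = self._by_arm.get(d.arm)
            if arm is None:
                raise PanelValidationError(
                    f"deficiency {d.stock_id!r}: unknown arm {d.arm!r}"
                )
            if d.end > arm.length:
                raise PanelValidationError(
                    f"deficiency {d.stock_id!r}: end {d.end} exceeds "
                    f"arm {arm.name} length {arm.length}"
                )
        if self.euchromatin is not None:
            for arm_name, ivs in self.euchromatin.items():
                arm = self._by_arm.get(arm_name)
                if arm is None:
                    raise PanelValidationError(f"euchromatin: unknown arm {arm_name!r}")
                for s, e in ivs:
                    if not 0 <= s < e <= arm.length:
                        raise PanelValidationError(
                            f"euchromatin on {arm_name}: bad interval [{s}, {e})"
                        )

    def arm(self, name: str) -> ChromosomeArm:
        return self._by_arm[name]

    @property
    def stock_ids(self) -> tuple[str, ...]:
        return tuple(d.stock_id for d in self.deficiencies)

    def deficiency(self, stock_id: str) -> Deficiency:
        for d in self.deficiencies:
            if d.stock_id == stock_id:
                return d
        raise KeyError(stock_id)


def _read_tsv_rows(path: str | Path, n_cols: int, what: str):
    """Yield (line_number, fields) for non-comment, non-blank TSV lines."""
    path = Path(path)
    if not path.exists():
        raise PanelValidationError(f"{what} file not found: {path}")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise PanelValidationError(
                    f"{what} line {lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise PanelValidationError(
            f"{what} line {lineno}: non-integer coordinate {value!r}"
        ) from None


def parse_arm_table(path: str | Path) -> tuple[ChromosomeArm, ...]:
    """Read an arm table: TSV ``arm  length  chromosome`` (header optional)."""
    arms = []
    for lineno, (name, length, chrom) in _read_tsv_rows(path, 3, "arm table"):
        if name == "arm" and lineno == 1:
            continue
        arms.append(ChromosomeArm(name, _parse_int(length, "arm table", lineno), chrom))
    if not arms:
        raise PanelValidationError(f"arm table {path}: no arms")
    return tuple(arms)


def parse_euchromatin(
    path: str | Path, arms: Sequence[ChromosomeArm]
) -> dict[str, tuple[tuple[int, int], ...]]:
    """Read a euchromatin table: TSV ``arm  start  end``."""
    out: dict[str, list[tuple[int, int]]] = {}
    for lineno, (arm, start, end) in _read_tsv_rows(path, 3, "euchromatin"):
        if arm == "arm" and lineno == 1:
            continue
        s = _parse_int(start, "euchromatin", lineno)
        e = _parse_int(end, "euchromatin", lineno)
        if e <= s:
            raise PanelValidationError(f"euchromatin line {lineno}: end <= start")
        out.setdefault(arm, []).append((s, e))
    return {k: tuple(v) for k, v in out.items()}


def parse_panel(
    path: str | Path,
    arm_table: str | Path | Sequence[ChromosomeArm] | None = None,
    euchromatin: str | Path | None = None,
) -> DeficiencyPanel:
    """Read a deficiency panel file into a validated :class:`DeficiencyPanel`.

    The panel file is a TSV with columns ``arm  start  end  stock_id``
    (BED-compatible column order with the stock id in column 4); ``#``-prefixed
    lines are ignored.  Row order is preserved.  Malformed rows, empty
    intervals, unknown arms and duplicate stock ids raise
    :class:`PanelValidationError` naming the offending line.
    """
    if arm_table is None:
        arms: tuple[ChromosomeArm, ...] = DEFAULT_ARMS
    elif isinstance(arm_table, (str, Path)):
        arms = parse_arm_table(arm_table)
    else:
        arms = tuple(arm_table)
    arm_names = {a.name for a in arms}

    defs: list[Deficiency] = []
    seen: set[str] = set()
    for lineno, (arm, start, end, stock_id) in _read_tsv_rows(path, 4, "panel"):
        if arm == "arm" and lineno == 1:
            continue
        s = _parse_int(start, "panel", lineno)
        e = _parse_int(end, "panel", lineno)
        if e <= s:
            raise PanelValidationError(
                f"panel line {lineno}: empty or inverted interval [{s}, {e})"
            )
        if arm not in arm_names:
            raise PanelValidationError(f"panel line {lineno}: unknown arm {arm!r}")
        if stock_id in seen:
            raise PanelValidationError(
                f"panel line {lineno}: duplicate stock_id {stock_id!r}"
            )
        seen.add(stock_id)
        defs.append(Deficiency(stock_id, arm, s, e))

    euch = None
    if euchromatin is not None:
        euch = parse_euchromatin(euchromatin, arms)
    return DeficiencyPanel(arms=arms, deficiencies=tuple(defs), euchromatin=euch)


def write_panel(panel: DeficiencyPanel, path: str | Path) -> None:
    """Write a panel to TSV in the ``arm  start  end  stock_id`` layout."""
    with open(path, "w") as fh:
        fh.write("#arm\tstart\tend\tstock_id\n")
        for d in panel.deficiencies:
            fh.write(f"{d.arm}\t{d.start}\t{d.end}\t{d.stock_id}\n")


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True iff half-open intervals ``a`` and ``b`` share at least one point.

    Abutting intervals ([0, 10) vs [10, 20)) do not overlap.
    """
    return a[0] < b[1] and b[0] < a[1]


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in ivs:
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def _clip(iv: tuple[int, int], window: tuple[int, int]) -> tuple[int, int] | None:
    s = max(iv[0], window[0])
    e = min(iv[1], window[1])
    return (s, e) if s < e else None


def coverage_fraction(panel: DeficiencyPanel) -> float:
    """Fraction of euchromatin covered by the union of the panel's deficiencies.

    Computed as ``|union of (deficiency ∩ euchromatin)| / |euchromatin|``,
    pooled over arms.  Requires the panel to carry a euchromatin table.
    """
    if panel.euchromatin is None:
        raise PanelValidationError("coverage_fraction requires a euchromatin table")
    euch_total = sum(
        e - s for ivs in panel.euchromatin.values() for s, e in ivs
    )
    if euch_total == 0:
        raise PanelValidationError("euchromatin table is empty")
    covered = 0
    for arm_name, euch_ivs in panel.euchromatin.items():
        clipped: list[tuple[int, int]] = []
        for d in panel.deficiencies:
            if d.arm != arm_name:
                continue
            for window in euch_ivs:
                c = _clip(d.interval, window)
                if c is not None:
                    clipped.append(c)
        covered += interval_union_length(clipped)
    return covered / euch_total
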