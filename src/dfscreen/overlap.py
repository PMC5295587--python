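"""Cross-condition overlap of HI sets and its randomization null.

Given the sets of HI-flagged stocks at two conditions (e.g. the two
rearing temperatures), the stocks testable in both conditions form the
universe; the sets are partitioned into shared and condition-specific
members, and the observed overlap is compared against the null in which
one set is replaced by a uniformly random subset of the same size drawn
from the universe.  Under that null the overlap is hypergeometric, so a
closed-form tail probability serves as the oracle for the Monte-Carlo
randomization p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .viability import HISet

__all__ = [
    "OverlapResult",
    "partition_hi_sets",
    "overlap_randomization_test",
    "hypergeometric_tail",
]


@dataclass(frozen=True)
class OverlapResult:
    """Set-partition counts and overlap-significance estimates."""

    n_universe: int
    n_a: int
    n_b: int
    n_both: int
    n_only_a: int
    n_only_b: int
    p_randomization: float | None = None
    permutations: int | None = None
    p_hypergeometric: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_counts(self.n_universe, self.n_a, self.n_b, self.n_both)
        assert self.n_only_a == self.n_a - self.n_both
        assert self.n_only_b == self.n_b - self.n_both


def _check_counts(n_universe: int, n_a: int, n_b: int, n_both: int) -> None:
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie in [0, n_universe]")
    if not 0 <= n_both <= min(n_a, n_b):
        raise ValueError("overlap must lie in [0, min(n_a, n_b)]")
    if n_both < n_a + n_b - n_universe:
        raise ValueError("overlap smaller than forced by set sizes")


def partition_hi_sets(a: HISet, b: HISet, universe: set[str]) -> OverlapResult:
    """Exact set arithmetic on stock ids restricted to a shared universe."""
    for name, s in (("a", a), ("b", b)):
        extra = s.members - universe
        if extra:
            raise ValueError(
                f"HI set {name} has members outside the universe: {sorted(extra)[:5]}"
            )
    both = a.members & b.members
    return OverlapResult(
        n_universe=len(universe),
        n_a=len(a.members),
        n_b=len(b.members),
        n_both=len(both),
        n_only_a=len(a.members - b.members),
        n_only_b=len(b.members - a.members),
    )


def hypergeometric_tail(n_universe: int, n_a: int, n_b: int, n_both: int) -> float:
    """P(X >= n_both) for X ~ Hypergeometric(n_universe, n_b, n_a).

    The closed-form limit of the randomization test: the overlap of a
    uniformly random size-``n_a`` subset with a fixed size-``n_b`` subset.
    ``n_both`` is a threshold, so values outside the feasible overlap range
    yield the degenerate tails 1 and 0.
    """
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie in [0, n_universe]")
    if n_both <= max(0, n_a + n_b - n_universe):
        return 1.0
    if n_both > min(n_a, n_b):
        return 0.0
    return float(stats.hypergeom.sf(n_both - 1, n_universe, n_b, n_a))


def overlap_randomization_test(
    n_universe: int,
    n_a: int,
    n_b: int,
    n_both: int,
    permutations: int = 100_000,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """Monte-Carlo p-value for the observed overlap of two stock sets.

    Null: redraw set *a* as a uniformly random subset of size ``n_a`` from
    the universe, holding *b* fixed; count replicates whose overlap with
    *b* is at least (``alternative="greater"``, enrichment, the default) or
    at most (``"less"``, depletion) the observed overlap.  Returns
    ``(1 + b) / (permutations + 1)``; deterministic given ``seed``.
    """
    _check_counts(n_universe, n_a, n_b, n_both)
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")

    rng = np.random.default_rng(seed)
    in_b = np.zeros(n_universe, dtype=bool)
    in_b[:n_b] = True  # which ids are in b is arbitrary under the null

    extreme = 0
    chunk = 20_000
    done = 0
    while done < permutations:
        m = min(chunk, permutations - done)
        if n_a == 0:
            overlaps = np.zeros(m, dtype=int)
        else:
            # uniformly random size-n_a subsets: top-n_a of iid uniforms
            u = rng.random((m, n_universe))
            picks = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
            overlaps = in_b[picks].sum(axis=1)
        if alternative == "greater":
            extreme += int((overlaps >= n_both).sum())
        else:
            extreme += int((overlaps <= n_both).sum())
        done += m
    return (1 + extreme) / (permutations + 1)
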