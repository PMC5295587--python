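"""Minimal causal-region counting and per-arm density testing.

Two deficiencies that overlap and both cause hybrid incompatibility may
uncover the same recessive allele, so the raw number of HI-flagged
deletions overstates the number of distinct loci.  Two corrections are
computed:

* **component count** — connected components of the interval-overlap graph
  (clusters of mutually linked deletions), found per arm by an end-point
  sweep;
* **minimal count** — the minimum number of point loci such that every HI
  interval contains at least one point (a minimum stabbing set), found per
  arm by the classic greedy rule: sort by interval end and place a point
  just inside the end of the first uncovered interval.  The greedy rule is
  exact for interval stabbing; a brute-force oracle is provided for small
  inputs as a regression guard.

A chain of pairwise-overlapping intervals with no common base forms one
component but needs two or more stabbing points, so in general
``component_count <= minimal_count <= number of intervals``.

The per-arm density of HI loci is tested against a uniform expectation
(same number of loci on every arm) with Pearson's chi-square statistic and
a simulated p-value obtained by multinomial resampling under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .viability import HISet

__all__ = [
    "Cluster",
    "LocusEstimate",
    "UniformityResult",
    "merge_overlapping_hi",
    "minimal_locus_count",
    "brute_force_min_cover",
    "arm_density_test",
]

ArmedInterval = tuple[str, int, int]  # (arm, start, end)


@dataclass(frozen=True)
class Cluster:
    """One connected overlap component: its arm, span, and member stocks."""

    arm: str
    span_start: int
    span_end: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class LocusEstimate:
    """Minimal causal-region summary for one HI set."""

    minimal_count: int
    component_count: int
    n_members: int
    representative_points: Mapping[str, tuple[int, ...]]
    clusters: tuple[Cluster, ...]
    per_arm_minimal: Mapping[str, int]

    def __post_init__(self) -> None:
        assert self.component_count <= self.minimal_count <= self.n_members


@dataclass(frozen=True)
class UniformityResult:
    """Simulated-p chi-square test of equal per-arm locus counts."""

    per_arm_counts: Mapping[str, int]
    statistic: float
    p_simulated: float
    replicates: int
    seed: int


def _intervals_by_arm(hi: HISet) -> dict[str, list[tuple[int, int, str]]]:
    by_arm: dict[str, list[tuple[int, int, str]]] = {}
    missing = hi.members - set(hi.intervals)
    if missing:
        raise ValueError(
            f"HI set members without interval annotation: {sorted(missing)[:5]}"
        )
    for stock_id in sorted(hi.members):
        arm, start, end = hi.intervals[stock_id]
        by_arm.setdefault(arm, []).append((start, end, stock_id))
    return by_arm


def merge_overlapping_hi(hi: HISet) -> tuple[int, tuple[Cluster, ...]]:
    """Connected components of the interval-overlap graph, per arm.

    Returns ``(component_count, clusters)``; each cluster records its arm,
    the union span of its members, and the member stock ids.  Computed by
    an end-point sweep: intervals sorted by start, a new component opens
    whenever the next interval starts at or beyond the running maximum end.
    """
    clusters: list[Cluster] = []
    for arm, ivs in sorted(_intervals_by_arm(hi).items()):
        ivs.sort()
        cur_members: list[str] = []
        cur_start = cur_end = 0
        for start, end, stock_id in ivs:
            if cur_members and start >= cur_end:
                clusters.append(Cluster(arm, cur_start, cur_end, tuple(cur_members)))
                cur_members = []
            if not cur_members:
                cur_start, cur_end = start, end
            cur_end = max(cur_end, end)
            cur_members.append(stock_id)
        if cur_members:
            clusters.append(Cluster(arm, cur_start, cur_end, tuple(cur_members)))
    return len(clusters), tuple(clusters)


def _greedy_stab(intervals: Sequence[tuple[int, int]]) -> list[int]:
    """Minimum stabbing points for half-open intervals (greedy, exact)."""
    points: list[int] = []
    last_point: int | None = None
    for start, end in sorted(intervals, key=lambda iv: iv[1]):
        if last_point is None or not (start <= last_point < end):
            last_point = end - 1
            points.append(last_point)
    return points


def minimal_locus_count(hi: HISet) -> LocusEstimate:
    """Minimum number of point loci explaining every HI interval.

    Per arm, the minimum stabbing set is computed greedily (sort by end;
    stab the first uncovered interval at ``end - 1``; skip every interval
    containing that point), then summed over arms.  Also reports the
    overlap-component count and representative stabbing coordinates.
    """
    component_count, clusters = merge_overlapping_hi(hi)
    rep: dict[str, tuple[int, ...]] = {}
    per_arm: dict[str, int] = {}
    for arm, ivs in sorted(_intervals_by_arm(hi).items()):
        points = _greedy_stab([(s, e) for s, e, _ in ivs])
        rep[arm] = tuple(points)
        per_arm[arm] = len(points)
    return LocusEstimate(
        minimal_count=sum(per_arm.values()),
        component_count=component_count,
        n_members=len(hi.members),
        representative_points=rep,
        clusters=clusters,
        per_arm_minimal=per_arm,
    )


def brute_force_min_cover(intervals: Sequence[tuple[int, int]]) -> int:
    """Exact minimum stabbing-set size by exhaustive search (test oracle).

    Candidate points are the interval ``end - 1`` coordinates (some optimal
    solution always uses only those).  Refuses inputs larger than 12
    intervals.
    """
    if len(intervals) > 12:
        raise ValueError("brute_force_min_cover is limited to <= 12 intervals")
    if not intervals:
        return 0
    candidates = sorted({end - 1 for _, end in intervals})
    for k in range(1, len(intervals) + 1):
        for pts in combinations(candidates, k):
            if all(any(s <= p < e for p in pts) for s, e in intervals):
                return k
    raise AssertionError("unreachable: full candidate set always covers")


def arm_density_test(
    per_arm_counts: Mapping[str, int],
    replicates: int = 2000,
    seed: int = 0,
) -> UniformityResult:
    """Test whether HI loci are uniformly distributed over arms.

    Pearson's chi-square statistic against equal expected counts per arm,
    with a simulated p-value: ``replicates`` multinomial draws of the total
    count over the arms under the uniform null, and
    ``p = (1 + #{replicate stat >= observed}) / (replicates + 1)``.
    """
    arms = sorted(per_arm_counts)
    counts = np.array([per_arm_counts[a] for a in arms], dtype=float)
    k = len(arms)
    n = counts.sum()
    if k < 2:
        raise ValueError("arm density test needs at least 2 arms")
    if n < 1:
        raise ValueError("arm density test needs a positive total count")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    expected = n / k
    statistic = float(((counts - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(n), np.full(k, 1.0 / k), size=replicates)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=1)
    # small tolerance so ties with the observed statistic count as extreme
    b = int((sim_stats >= statistic - 1e-12).sum())
    p_simulated = (1 + b) / (replicates + 1)
    return UniformityResult(
        per_arm_counts=dict(per_arm_counts),
        statistic=statistic,
        p_simulated=p_simulated,
        replicates=replicates,
        seed=seed,
    )
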