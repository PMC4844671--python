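"""Competitive-hierarchy inference from an invasion network.

Strains are assigned integer hierarchy levels (larger = higher rank).  A
candidate assignment is scored by walking every observed directed invasion
i -> j: invasions pointing down the hierarchy (h_i > h_j) earn a reward,
invasions directed against the hierarchy (h_i < h_j) a penalty, and
invasions between equal-level strains score zero.  The optimal hierarchy
is the assignment (or set of co-optimal assignments) maximizing the total
score; for the 18-strain panel this kind of scheme places strains into a
small number of levels with mutually bistable strains sharing the top.

Two optimizers are provided: an exhaustive search over all canonical level
assignments (exact, n <= 7) and a multi-restart greedy hill-climb on
single-strain level moves (the workhorse for larger panels).  A variant
recomputes the hierarchy with all inhibited pairs excluded from the score,
averaging levels across the co-optimal assignments, which probes whether
the hierarchy is shaped by inhibition itself or by a common factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .networks import INVADES, InhibitionMatrix, InvasionMatrix

__all__ = [
    "HierarchyAssignment",
    "ScoreParams",
    "HierarchySolution",
    "score_hierarchy",
    "canonicalize_levels",
    "exhaustive_optimal",
    "search_optimal",
    "hierarchy_excluding_inhibition",
]

HierarchyAssignment = dict[str, int]

_EXHAUSTIVE_MAX_N = 7


@dataclass(frozen=True)
class ScoreParams:
    """Scoring weights for hierarchy assignments.

    reward: added per invasion pointing down the hierarchy (> 0).
    penalty: added per invasion against the hierarchy (< 0).
    gap_weighted: if True the penalty scales with the level gap climbed;
        by default each offending invasion costs one unit regardless of gap.
    """

    reward: float = 1.0
    penalty: float = -1.0
    gap_weighted: bool = False

    def __post_init__(self):
        if self.reward <= 0:
            raise ValueError("reward must be > 0")
        if self.penalty >= 0:
            raise ValueError("penalty must be < 0")


@dataclass
class HierarchySolution:
    """Co-optimal canonical assignments and search metadata."""

    assignments: list[HierarchyAssignment]
    score: float
    method: str
    n_restarts: int | None = None
    fraction_optimal: float | None = None
    seed: int | None = None

    @property
    def n_levels(self) -> int:
        return max(max(a.values()) for a in self.assignments)

    def mean_levels(self) -> dict[str, float]:
        """Per-strain level averaged over the unique co-optimal assignments."""
        strains = list(self.assignments[0])
        return {
            s: float(np.mean([a[s] for a in self.assignments])) for s in strains
        }


def _edges(inv: InvasionMatrix, pair_mask: np.ndarray | None = None) -> np.ndarray:
    """(m, 2) array of directed INVADES edges, optionally masked by an
    (n, n) symmetric pair-inclusion mask."""
    keep = inv.entries == INVADES
    if pair_mask is not None:
        keep &= pair_mask
    return np.argwhere(keep)


def _levels_array(inv: InvasionMatrix, h: HierarchyAssignment) -> np.ndarray:
    try:
        return np.array([h[s] for s in inv.strains], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"no hierarchy level for strain {e.args[0]!r}") from None


def _score_vec(levels: np.ndarray, edges: np.ndarray, p: ScoreParams) -> float:
    if len(edges) == 0:
        return 0.0
    hi = levels[edges[:, 0]]
    hj = levels[edges[:, 1]]
    down = hi > hj
    up = hi < hj
    if p.gap_weighted:
        pen = p.penalty * (hj - hi)[up].sum()
    else:
        pen = p.penalty * up.sum()
    return float(p.reward * down.sum() + pen)


def score_hierarchy(
    inv: InvasionMatrix,
    h: HierarchyAssignment,
    p: ScoreParams = ScoreParams(),
) -> float:
    """Score an assignment: sum of rewards for downward invasions and
    penalties for upward ones; missing entries and equal-level invasions
    contribute nothing."""
    return _score_vec(_levels_array(inv, h), _edges(inv), p)


def canonicalize_levels(h: HierarchyAssignment) -> HierarchyAssignment:
    """Relabel levels order-preservingly onto 1..L with no gaps."""
    distinct = sorted(set(h.values()))
    remap = {old: new for new, old in enumerate(distinct, start=1)}
    return {s: remap[v] for s, v in h.items()}


def _canonical_tuple(levels: np.ndarray) -> tuple[int, ...]:
    distinct = np.unique(levels)
    remap = {int(v): i + 1 for i, v in enumerate(distinct)}
    return tuple(remap[int(v)] for v in levels)


def exhaustive_optimal(
    inv: InvasionMatrix,
    p: ScoreParams = ScoreParams(),
    pair_mask: np.ndarray | None = None,
) -> HierarchySolution:
    """Exact set of canonical co-optimal assignments by enumeration.

    Enumerates every assignment of levels 1..n (canonicalization makes the
    bound lossless); refuses above n = 7 where the space exceeds ~2 x 10^6.
    """
    n = inv.n
    if n > _EXHAUSTIVE_MAX_N:
        raise ValueError(
            f"exhaustive search supports n <= {_EXHAUSTIVE_MAX_N} (got {n}); "
            "use search_optimal"
        )
    edges = _edges(inv, pair_mask)
    # all n^n level vectors, scored in a vectorized sweep
    grids = np.meshgrid(*[np.arange(1, n + 1, dtype=np.int8)] * n, indexing="ij")
    levels = np.stack([g.ravel() for g in grids], axis=1)
    if len(edges) == 0:
        scores = np.zeros(len(levels))
    else:
        hi = levels[:, edges[:, 0]]
        hj = levels[:, edges[:, 1]]
        down = (hi > hj).sum(axis=1)
        if p.gap_weighted:
            pen = p.penalty * np.where(hi < hj, hj - hi, 0).sum(axis=1)
        else:
            pen = p.penalty * (hi < hj).sum(axis=1)
        scores = p.reward * down + pen
    best = scores.max()
    winners = levels[scores == best]
    unique = {_canonical_tuple(w) for w in winners}
    assignments = [
        dict(zip(inv.strains.ids, t)) for t in sorted(unique)
    ]
    return HierarchySolution(assignments, float(best), method="exhaustive")


def _greedy_climb(
    levels: np.ndarray,
    edges: np.ndarray,
    n: int,
    p: ScoreParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Hill-climb on single-strain level moves and pairwise level swaps,
    first improvement in a seeded random scan, until a local optimum.

    Swap moves escape the common trap where two strains share a level and
    the only free level is far from both."""
    score = _score_vec(levels, edges, p)
    incident = [
        np.flatnonzero((edges[:, 0] == s) | (edges[:, 1] == s)) for s in range(n)
    ]

    def contribution(idx: np.ndarray, lv: np.ndarray) -> float:
        return sum(_term(lv[i], lv[j], p) for i, j in edges[idx])

    def try_apply(strains: tuple[int, ...], new_levels: tuple[int, ...]) -> float:
        idx = np.unique(np.concatenate([incident[s] for s in strains])) if strains else []
        before = contribution(idx, levels)
        saved = [levels[s] for s in strains]
        for s, l in zip(strains, new_levels):
            levels[s] = l
        d = contribution(idx, levels) - before
        if d > 1e-12:
            return d
        for s, l in zip(strains, saved):
            levels[s] = l
        return 0.0

    improved = True
    while improved:
        improved = False
        moves = [("m", s, l) for s in range(n) for l in range(1, n + 1)]
        moves += [("x", s, t) for s in range(n) for t in range(s + 1, n)]
        rng.shuffle(moves)
        for kind, a, b in moves:
            if kind == "m":
                if b == levels[a]:
                    continue
                d = try_apply((a,), (b,))
            else:
                if levels[a] == levels[b]:
                    continue
                d = try_apply((a, b), (int(levels[b]), int(levels[a])))
            if d:
                score += d
                improved = True
                break
    return levels, score


def _term(hi: int, hj: int, p: ScoreParams) -> float:
    if hi > hj:
        return p.reward
    if hi < hj:
        return p.penalty * (hj - hi) if p.gap_weighted else p.penalty
    return 0.0


def search_optimal(
    inv: InvasionMatrix,
    p: ScoreParams = ScoreParams(),
    n_restarts: int = 1000,
    rng: np.random.Generator | int | None = None,
    pair_mask: np.ndarray | None = None,
) -> HierarchySolution:
    """Stochastic search: random restarts of greedy hill-climbing.

    Each restart starts from uniform random levels in 1..n and climbs by
    single-strain level moves to a local optimum.  Returns the best score
    found, the deduplicated canonical co-optimal assignments attaining it,
    and the fraction of restarts that reached it.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seed = rng if isinstance(rng, (int, type(None))) else None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = inv.n
    edges = _edges(inv, pair_mask)
    best_score = -np.inf
    winners: set[tuple[int, ...]] = set()
    hits = 0
    for _ in range(n_restarts):
        levels = rng.permutation(n) + 1  # random initial ranking
        levels, score = _greedy_climb(levels, edges, n, p, rng)
        if score > best_score + 1e-9:
            best_score = score
            winners = {_canonical_tuple(levels)}
            hits = 1
        elif abs(score - best_score) <= 1e-9:
            winners.add(_canonical_tuple(levels))
            hits += 1
    assignments = [dict(zip(inv.strains.ids, t)) for t in sorted(winners)]
    return HierarchySolution(
        assignments,
        float(best_score),
        method="restart-greedy",
        n_restarts=n_restarts,
        fraction_optimal=hits / n_restarts,
        seed=seed,
    )


def uninhibited_pair_mask(inv: InvasionMatrix, inh: InhibitionMatrix) -> np.ndarray:
    """Symmetric mask of pairs with no inhibition in either direction."""
    if inh.strains != inv.strains:
        raise ValueError("invasion and inhibition matrices must share a StrainSet")
    inhibited = (inh.entries == 1) | (inh.entries.T == 1)
    return ~inhibited


def hierarchy_excluding_inhibition(
    inv: InvasionMatrix,
    inh: InhibitionMatrix,
    p: ScoreParams = ScoreParams(),
    n_restarts: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, float], HierarchySolution]:
    """Hierarchy with inhibited pairs removed from the score.

    Invasions within any pair showing inhibition in either direction do
    not contribute; scoring ties are frequent, so the per-strain level is
    averaged over all unique canonical co-optimal assignments found.
    Returns (mean levels, full solution).  Uses exhaustive enumeration
    when n allows, otherwise the restart search.
    """
    mask = uninhibited_pair_mask(inv, inh)
    if inv.n <= _EXHAUSTIVE_MAX_N:
        sol = exhaustive_optimal(inv, p, pair_mask=mask)
    else:
        sol = search_optimal(inv, p, n_restarts=n_restarts, rng=rng, pair_mask=mask)
    return sol.mean_levels(), sol
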