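"""Permutation tests linking invasion-network features to inhibition.

All inference here is permutation-based.  The null model for inhibition
randomizes the inhibition matrix while keeping the number of each pairwise
link type (0, 1 or 2 inhibitions) fixed; the null for invasion-network
structure keeps the number of each pairwise invasion link type fixed
(see :func:`invnet.motifs.randomize_preserving_pair_types`).  Empirical
p-values use the add-one convention p = (1 + #extreme) / (1 + n_perm) so
they are never exactly zero.

Tests provided, with their one-sided directions:

* resident protection — residents that inhibit a would-be invader are less
  likely to be invaded (extreme = ratio <= observed);
* invader advantage — inhibiting the resident raises the chance to invade
  (extreme = ratio >= observed);
* gap-controlled invader test — the invader-advantage question restricted
  to ordered pairs a small number of hierarchy levels apart, with the
  permutation preserving the number of inhibitions pointing up and down
  the hierarchy (controls for the downward bias of inhibition, i.e.
  Simpson's paradox);
* hubs of bistability — is bistability concentrated on a few strains?
* bistability enrichment — are pairs with an inhibitory interaction more
  often bistable?

Ordered pairs with a missing entry in either matrix are excluded pairwise
and the exclusions reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hierarchy import HierarchyAssignment
from .motifs import randomize_preserving_pair_types
from .networks import (
    INVADES,
    MISSING,
    InhibitionMatrix,
    InvasionMatrix,
    PairCategory,
    bistability_degrees,
)

__all__ = [
    "ContingencyTable2x2",
    "PermutationTestResult",
    "randomize_inhibition",
    "enrichment_ratio",
    "resident_protection_test",
    "invader_advantage_test",
    "gap_controlled_invader_test",
    "hubs_of_bistability_test",
    "bistability_inhibition_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Ordered-pair contingency of inhibition against invasion.

    Cells: a = (inhibited, invaded), b = (inhibited, not invaded),
    c = (not inhibited, invaded), d = (not inhibited, not invaded).
    """

    a: int
    b: int
    c: int
    d: int
    description: str = ""

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class PermutationTestResult:
    observed: float
    direction: str  # "le" or "ge": which tail counts as extreme
    n_perm: int
    p_value: float
    seed: int | None = None
    table: ContingencyTable2x2 | None = None
    n_excluded_pairs: int = 0
    excluded_strains: tuple[str, ...] = ()
    haldane_corrected: bool = False


def _as_rng(rng) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, np.random.Generator):
        return rng, None
    return np.random.default_rng(rng), rng


def _empirical_p(extreme: int, n_perm: int) -> float:
    return (1 + extreme) / (1 + n_perm)


def randomize_inhibition(
    inh: InhibitionMatrix, rng: np.random.Generator | int
) -> InhibitionMatrix:
    """Random inhibition matrix preserving the number of each pairwise link
    type (0, 1 or 2 inhibitions) over complete pairs; single inhibitions
    get a uniform random direction, placement is a uniform permutation."""
    out = randomize_preserving_pair_types(
        InvasionMatrix(inh.strains, inh.entries), rng
    )
    return InhibitionMatrix(inh.strains, out.entries)


def enrichment_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Ratio of invasion odds with inhibition to invasion odds without:
    (a/b) / (c/d).  When any cell is zero, 0.5 is added to every cell
    (Haldane correction) and the correction is flagged in the second
    return value."""
    a, b, c, d = (float(table.a), float(table.b), float(table.c), float(table.d))
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d), corrected


def _shared_valid(inh: InhibitionMatrix, inv: InvasionMatrix) -> np.ndarray:
    if inh.strains != inv.strains:
        raise ValueError("matrices must share a StrainSet")
    valid = (inh.entries != MISSING) & (inv.entries != MISSING) & (inv.entries.T != MISSING)
    np.fill_diagonal(valid, False)
    return valid


def _contingency(
    inh_entries: np.ndarray,
    invaded: np.ndarray,
    valid: np.ndarray,
    description: str,
) -> ContingencyTable2x2:
    inhibits = inh_entries == 1
    return ContingencyTable2x2(
        a=int((valid & inhibits & invaded).sum()),
        b=int((valid & inhibits & ~invaded).sum()),
        c=int((valid & ~inhibits & invaded).sum()),
        d=int((valid & ~inhibits & ~invaded).sum()),
        description=description,
    )


def _inhibition_invasion_test(
    inh: InhibitionMatrix,
    inv: InvasionMatrix,
    invaded: np.ndarray,
    direction: str,
    description: str,
    n_perm: int,
    rng,
) -> PermutationTestResult:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng, seed = _as_rng(rng)
    valid = _shared_valid(inh, inv)
    if not (valid & (inh.entries == 1)).any():
        raise ValueError("degenerate test: no inhibited ordered pairs")
    table = _contingency(inh.entries, invaded, valid, description)
    obs, corrected = enrichment_ratio(table)
    extreme = 0
    for _ in range(n_perm):
        null = randomize_inhibition(inh, rng)
        # the null preserves the missing-entry pattern, so `valid` carries over
        stat, _ = enrichment_ratio(
            _contingency(null.entries, invaded, valid, description)
        )
        if (direction == "le" and stat <= obs) or (direction == "ge" and stat >= obs):
            extreme += 1
    n_total = inh.n * (inh.n - 1)
    return PermutationTestResult(
        observed=obs,
        direction=direction,
        n_perm=n_perm,
        p_value=_empirical_p(extreme, n_perm),
        seed=seed,
        table=table,
        n_excluded_pairs=int(n_total - valid.sum()),
        haldane_corrected=corrected,
    )


def resident_protection_test(
    inh: InhibitionMatrix,
    inv: InvasionMatrix,
    n_perm: int,
    rng: np.random.Generator | int,
) -> PermutationTestResult:
    """Does inhibiting a strain protect against being invaded by it?

    For every ordered pair (A, B): does A inhibit B, and does B invade A?
    The alternative is protection, i.e. an enrichment ratio below what
    random inhibition networks produce (extreme = ratio <= observed).
    """
    invaded = inv.entries.T == INVADES  # B invades A at position (A, B)
    return _inhibition_invasion_test(
        inh, inv, invaded, "le", "A inhibits B vs B invades A", n_perm, rng
    )


def invader_advantage_test(
    inh: InhibitionMatrix,
    inv: InvasionMatrix,
    n_perm: int,
    rng: np.random.Generator | int,
) -> PermutationTestResult:
    """Does inhibiting the resident help a rare strain invade it?

    For every ordered pair (A, B): does A inhibit B, and does A invade B?
    Alternative: inhibitors invade more (extreme = ratio >= observed).
    """
    invaded = inv.entries == INVADES
    return _inhibition_invasion_test(
        inh, inv, invaded, "ge", "A inhibits B vs A invades B", n_perm, rng
    )


def gap_controlled_invader_test(
    inh: InhibitionMatrix,
    inv: InvasionMatrix,
    h: HierarchyAssignment,
    n_perm: int,
    rng: np.random.Generator | int,
    gap_max: int = 3,
) -> PermutationTestResult:
    """Invader-advantage question controlled for hierarchy position.

    Only ordered pairs (A, B) with 0 < h(A) - h(B) <= gap_max are kept, so
    that invader and resident sit a comparable number of levels apart.
    The permutation shuffles which of the restricted pairs carry an
    inhibition while preserving the number of inhibitions pointing down
    (A -> B) and up (B -> A) the hierarchy within that set.  Alternative:
    inhibitors are *less* likely to invade (extreme = ratio <= observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng, seed = _as_rng(rng)
    valid = _shared_valid(inh, inv)
    levels = np.array([h[s] for s in inv.strains])
    gap = levels[:, None] - levels[None, :]
    sel = valid & (gap > 0) & (gap <= gap_max)
    pairs = np.argwhere(sel)
    if len(pairs) == 0:
        raise ValueError("no ordered pairs within the requested hierarchy gap")
    down_inh = inh.entries[pairs[:, 0], pairs[:, 1]] == 1  # A inhibits B
    up_inh = inh.entries[pairs[:, 1], pairs[:, 0]] == 1    # B inhibits A
    invades = inv.entries[pairs[:, 0], pairs[:, 1]] == INVADES
    if not down_inh.any():
        raise ValueError("degenerate test: no inhibitions within the restricted pairs")

    def stat(d: np.ndarray) -> float:
        t = ContingencyTable2x2(
            a=int((d & invades).sum()),
            b=int((d & ~invades).sum()),
            c=int((~d & invades).sum()),
            d=int((~d & ~invades).sum()),
        )
        return enrichment_ratio(t)[0]

    obs_table = ContingencyTable2x2(
        a=int((down_inh & invades).sum()),
        b=int((down_inh & ~invades).sum()),
        c=int((~down_inh & invades).sum()),
        d=int((~down_inh & ~invades).sum()),
        description=f"restricted to 0 < h(A)-h(B) <= {gap_max}",
    )
    obs, corrected = enrichment_ratio(obs_table)
    extreme = 0
    for _ in range(n_perm):
        d = down_inh[rng.permutation(len(down_inh))]
        # up-pointing inhibitions are permuted independently; they do not
        # enter the statistic but their count is preserved by construction
        if stat(d) <= obs:
            extreme += 1
    return PermutationTestResult(
        observed=obs,
        direction="le",
        n_perm=n_perm,
        p_value=_empirical_p(extreme, n_perm),
        seed=seed,
        table=obs_table,
        n_excluded_pairs=int(inh.n * (inh.n - 1) - len(pairs)),
        haldane_corrected=corrected,
    )


def top_k_bistability(inv: InvasionMatrix, top_k: int = 3) -> int:
    """Sum of the top_k largest per-strain bistability degrees."""
    degs = sorted(bistability_degrees(inv).values(), reverse=True)
    return int(sum(degs[:top_k]))


def hubs_of_bistability_test(
    inv: InvasionMatrix,
    n_perm: int,
    rng: np.random.Generator | int,
    top_k: int = 3,
) -> PermutationTestResult:
    """Are bistable links concentrated on a few hub strains?

    Statistic: the summed bistability degree of the top_k most bistable
    strains.  Null: invasion networks with the same number of each
    pairwise link type.  Extreme = null sum >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if inv.n < top_k:
        raise ValueError(f"need at least top_k={top_k} strains, got {inv.n}")
    rng, seed = _as_rng(rng)
    obs = top_k_bistability(inv, top_k)
    extreme = 0
    for _ in range(n_perm):
        null = randomize_preserving_pair_types(inv, rng)
        if top_k_bistability(null, top_k) >= obs:
            extreme += 1
    return PermutationTestResult(
        observed=float(obs),
        direction="ge",
        n_perm=n_perm,
        p_value=_empirical_p(extreme, n_perm),
        seed=seed,
    )


def _bistability_enrichment_stat(
    inh_entries: np.ndarray, bistable: np.ndarray, valid_pair: np.ndarray
) -> float:
    """(fraction of inhibition-bearing pairs that are bistable) /
    (fraction of inhibition-free pairs that are bistable), over unordered
    complete pairs (upper-triangle masks)."""
    has_inh = (inh_entries == 1) | (inh_entries.T == 1)
    with_inh = valid_pair & has_inh
    without = valid_pair & ~has_inh
    f_with = bistable[with_inh].mean() if with_inh.any() else np.nan
    f_without = bistable[without].mean() if without.any() else np.nan
    if f_without == 0:
        return np.inf if f_with > 0 else 1.0
    return float(f_with / f_without)


def bistability_inhibition_test(
    inh: InhibitionMatrix,
    inv: InvasionMatrix,
    n_perm: int,
    rng: np.random.Generator | int,
    exclude: tuple[str, ...] | list[str] = (),
) -> PermutationTestResult:
    """Is bistability enriched among pairs with an inhibitory interaction?

    A pair "has inhibition" if either direction inhibits.  The statistic
    is the bistable fraction among inhibition-bearing pairs divided by the
    bistable fraction among inhibition-free pairs; the null randomizes the
    inhibition matrix preserving pairwise link-type counts.  Extreme =
    null enrichment strictly greater than observed.  ``exclude`` drops
    strains (e.g. outliers at the bottom of the hierarchy) from both
    matrices first.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng, seed = _as_rng(rng)
    if exclude:
        keep = [s for s in inv.strains if s not in exclude]
        idx = [inv.strains.index(s) for s in keep]
        inv = InvasionMatrix(keep, inv.entries[np.ix_(idx, idx)])
        inh = InhibitionMatrix(keep, inh.entries[np.ix_(idx, idx)])
    n = inv.n
    # unordered complete pairs in both matrices (upper triangle)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    valid_pair = upper & inv.complete_pair_mask() & inh.complete_pair_mask()
    bistable = (inv.entries == 0) & (inv.entries.T == 0)
    has_inh = (inh.entries == 1) | (inh.entries.T == 1)
    n_with = int((valid_pair & has_inh).sum())
    n_without = int((valid_pair & ~has_inh).sum())
    if n_with == 0 or n_without == 0:
        raise ValueError(
            "degenerate test: all pairs fall in one inhibition class"
        )
    obs = _bistability_enrichment_stat(inh.entries, bistable, valid_pair)
    extreme = 0
    for _ in range(n_perm):
        null = randomize_inhibition(inh, rng)
        if _bistability_enrichment_stat(null.entries, bistable, valid_pair) > obs:
            extreme += 1
    return PermutationTestResult(
        observed=obs,
        direction="gt",
        n_perm=n_perm,
        p_value=_empirical_p(extreme, n_perm),
        seed=seed,
        excluded_strains=tuple(exclude),
        n_excluded_pairs=int(upper.sum() - valid_pair.sum()),
    )
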