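"""Triplet-motif census and enrichment for invasion networks.

Each unordered pair of strains carries one of four link types — no
invasion (bistable), a single invasion in either direction, or mutual
invasion (coexistence).  Up to relabeling of the three strains, a triple
can therefore realise exactly 16 distinct configurations; these are the
classical directed-graph triad types and are named here by their standard
MAN (mutual/asymmetric/null) codes, 003 through 300.  The census counts
triples per class; enrichment compares the observed census to random
networks that keep the number of each pairwise link type (0, 1 or 2
invasions) but shuffle their placement and re-draw the direction of single
invasions.

Triples containing any missing ordered entry are excluded from both the
observed and the null censuses, and the nulls randomize only over complete
pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .networks import INVADES, MISSING, NO_INVASION, InvasionMatrix

__all__ = [
    "MotifClass",
    "TriadCensus",
    "EnrichmentResult",
    "enumerate_motif_classes",
    "canonical_motif",
    "pair_state_matrix",
    "triad_census",
    "randomize_preserving_pair_types",
    "motif_enrichment",
    "PAIR_NONE",
    "PAIR_FORWARD",
    "PAIR_BACKWARD",
    "PAIR_MUTUAL",
]

# Link type of an unordered pair (i, j) with i < j.
PAIR_NONE = 0      # neither invades: bistable
PAIR_FORWARD = 1   # i invades j only
PAIR_BACKWARD = 2  # j invades i only
PAIR_MUTUAL = 3    # mutual invasion: coexistence

_PAIR_SLOTS = ((0, 1), (0, 2), (1, 2))
_PERMS = tuple(itertools.permutations(range(3)))

_DESCRIPTIONS = {
    "003": "all-bistable: no invasions among the triple",
    "012": "single invasion, two bistable pairs",
    "102": "one mutually invading pair, two bistable pairs",
    "021D": "one strain invades both others (divergent)",
    "021U": "both strains invade the same target (convergent)",
    "021C": "invasion chain A->B->C without closure",
    "111D": "mutual pair plus an invasion into it",
    "111U": "mutual pair plus an invasion out of it",
    "030T": "transitive hierarchy triangle",
    "030C": "cyclic dominance (rock-paper-scissors)",
    "201": "two mutual pairs, one bistable pair",
    "120D": "mutual pair, third strain invades both members",
    "120U": "mutual pair, both members invade the third",
    "120C": "mutual pair on an invasion chain",
    "210": "two mutual pairs plus a single invasion",
    "300": "all three pairs mutually invading",
}


@dataclass(frozen=True)
class MotifClass:
    """One of the 16 triad isomorphism classes.

    ``multiplicity`` is the number of labeled pair-state assignments (out
    of 4^3 = 64) that fall in this class.
    """

    code: str
    description: str
    multiplicity: int


@dataclass
class TriadCensus:
    """Counts of triples per motif class over a single invasion network."""

    counts: dict[str, int]
    n: int
    n_excluded_triples: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c.code] for c in enumerate_motif_classes()])


@dataclass
class EnrichmentResult:
    """Per-class motif enrichment against pair-type-preserving nulls."""

    observed: dict[str, int]
    null_mean: dict[str, float]
    p_enriched: dict[str, float]
    p_depleted: dict[str, float]
    n_null: int
    seed: int | None = None

    def direction(self, code: str) -> str:
        obs, mean = self.observed[code], self.null_mean[code]
        return "enriched" if obs > mean else ("depleted" if obs < mean else "neutral")


def _config_adjacency(states: tuple[int, int, int]) -> np.ndarray:
    a = np.zeros((3, 3), dtype=np.int8)
    for (i, j), s in zip(_PAIR_SLOTS, states):
        if s in (PAIR_FORWARD, PAIR_MUTUAL):
            a[i, j] = 1
        if s in (PAIR_BACKWARD, PAIR_MUTUAL):
            a[j, i] = 1
    return a


def _canonical_key(states: tuple[int, int, int]) -> tuple[int, ...]:
    a = _config_adjacency(states)
    return min(tuple(a[np.ix_(p, p)].ravel()) for p in _PERMS)


def _man_code(states: tuple[int, int, int]) -> str:
    # standard MAN label: counts of Mutual/Asymmetric/Null dyads plus the
    # orientation flag (Down/Up/Cyclic/Transitive) where needed
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    a = _config_adjacency(states)
    g.add_edges_from(zip(*np.nonzero(a)))
    return nx.triads.triad_type(g)


def _build_class_table() -> tuple[list[MotifClass], np.ndarray]:
    by_key: dict[tuple[int, ...], list[tuple[int, int, int]]] = {}
    for states in itertools.product(range(4), repeat=3):
        by_key.setdefault(_canonical_key(states), []).append(states)
    classes: dict[str, MotifClass] = {}
    table = np.empty((4, 4, 4), dtype=np.int64)
    order = [
        "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
        "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
    ]
    for key, members in by_key.items():
        code = _man_code(members[0])
        classes[code] = MotifClass(code, _DESCRIPTIONS[code], len(members))
    ordered = [classes[c] for c in order]
    index = {c: i for i, c in enumerate(order)}
    for states in itertools.product(range(4), repeat=3):
        table[states] = index[_man_code(states)]
    return ordered, table


_CLASSES, _CLASS_TABLE = _build_class_table()
_CODE_INDEX = {c.code: i for i, c in enumerate(_CLASSES)}


def enumerate_motif_classes() -> list[MotifClass]:
    """The 16 triad classes of a 3-strain invasion network.

    Classes partition all 4^3 = 64 labeled assignments of the three pair
    link types under node relabeling; multiplicities sum to 64.
    """
    return list(_CLASSES)


def canonical_motif(states: tuple[int, int, int] | list[int]) -> MotifClass:
    """Map the three pair link types of a labeled triple to its class.

    ``states`` gives the link type of pairs (0,1), (0,2), (1,2) in the
    PAIR_* encoding.
    """
    states = tuple(int(s) for s in states)
    if len(states) != 3 or any(s not in range(4) for s in states):
        raise ValueError(f"states must be three values in 0..3, got {states!r}")
    return _CLASSES[_CLASS_TABLE[states]]


def pair_state_matrix(inv: InvasionMatrix) -> np.ndarray:
    """Strictly-upper-triangular (n, n) matrix of pair link types.

    Entry [i, j] for i < j is the PAIR_* type of the unordered pair, or -1
    if either ordered entry is missing.  The lower triangle and diagonal
    are -1.
    """
    e = inv.entries
    fwd = e == INVADES
    bwd = e.T == INVADES
    state = fwd.astype(np.int8) + 2 * bwd.astype(np.int8)
    state[(e == MISSING) | (e.T == MISSING)] = -1
    state[np.tril_indices(inv.n)] = -1
    return state


def _triple_index(n: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)


def triad_census(inv: InvasionMatrix) -> TriadCensus:
    """Count every complete triple of strains by motif class.

    Triples touching a missing ordered entry are excluded and their number
    reported; with no missing data the counts sum to C(n, 3).
    """
    s = pair_state_matrix(inv)
    counts, excluded = _census_from_states(s, inv.n)
    return TriadCensus(
        counts={c.code: int(v) for c, v in zip(_CLASSES, counts)},
        n=inv.n,
        n_excluded_triples=int(excluded),
    )


def _census_from_states(s: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    if n < 3:
        return np.zeros(16, dtype=np.int64), 0
    t = _triple_index(n)
    s01 = s[t[:, 0], t[:, 1]]
    s02 = s[t[:, 0], t[:, 2]]
    s12 = s[t[:, 1], t[:, 2]]
    ok = (s01 >= 0) & (s02 >= 0) & (s12 >= 0)
    idx = _CLASS_TABLE[s01[ok], s02[ok], s12[ok]]
    return np.bincount(idx, minlength=16), int((~ok).sum())


def _as_rng(rng: np.random.Generator | int | None) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, np.random.Generator):
        return rng, None
    seed = rng
    return np.random.default_rng(seed), seed


def randomize_preserving_pair_types(
    inv: InvasionMatrix, rng: np.random.Generator | int
) -> InvasionMatrix:
    """Random network with the same number of each pairwise link type.

    The multiset of unordered pair categories (0, 1 or 2 invasions) over
    complete pairs is preserved exactly; categories are placed on pairs by
    a uniform permutation and single invasions receive a uniformly random
    direction.  Incomplete pairs are left untouched.
    """
    rng, _ = _as_rng(rng)
    s = pair_state_matrix(inv)
    rows, cols = np.nonzero(s >= 0)
    states = s[rows, cols]
    # category: 0 = bistable, 1 = single invasion, 2 = mutual
    cats = np.where(states == PAIR_MUTUAL, 2, np.where(states == PAIR_NONE, 0, 1))
    cats = cats[rng.permutation(len(cats))]
    entries = inv.entries.copy()
    for i, j, c in zip(rows, cols, cats):
        if c == 0:
            a = b = NO_INVASION
        elif c == 2:
            a = b = INVADES
        else:
            a, b = (INVADES, NO_INVASION) if rng.random() < 0.5 else (NO_INVASION, INVADES)
        entries[i, j] = a
        entries[j, i] = b
    return InvasionMatrix(inv.strains, entries)


def motif_enrichment(
    inv: InvasionMatrix,
    n_null: int,
    rng: np.random.Generator | int,
) -> EnrichmentResult:
    """Per-class enrichment/depletion versus the pair-type-preserving null.

    Empirical p-values use the add-one convention
    p = (1 + #{null >= observed}) / (1 + n_null) for enrichment, and the
    mirror for depletion, so that p is never exactly zero.
    """
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    rng, seed = _as_rng(rng)
    obs, _ = _census_from_states(pair_state_matrix(inv), inv.n)
    ge = np.zeros(16, dtype=np.int64)
    le = np.zeros(16, dtype=np.int64)
    total = np.zeros(16, dtype=np.float64)
    for _ in range(n_null):
        null = randomize_preserving_pair_types(inv, rng)
        c, _ = _census_from_states(pair_state_matrix(null), null.n)
        ge += c >= obs
        le += c <= obs
        total += c
    codes = [c.code for c in _CLASSES]
    return EnrichmentResult(
        observed={k: int(v) for k, v in zip(codes, obs)},
        null_mean={k: float(v) / n_null for k, v in zip(codes, total)},
        p_enriched={k: (1 + int(g)) / (1 + n_null) for k, g in zip(codes, ge)},
        p_depleted={k: (1 + int(l)) / (1 + n_null) for k, l in zip(codes, le)},
        n_null=n_null,
        seed=seed,
    )
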