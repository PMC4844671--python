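"""Synthetic-data generators with known ground truth.

Every input the analysis consumes can be generated here: invasion
matrices with a controllable mix of bistable / hierarchical / coexisting
pairs, matrices with a planted hierarchy, inhibition matrices biased to
point down a hierarchy, community models for the inhibition-zone
dynamics, and dual-indexed read-count tables with multinomial sampling
noise and i7 index hopping at a stated rate.

Defaults emulate the statistical structure of a pairwise invasion screen
among antibiotic-producing soil bacteria: a pair-category mix dominated by
bistable and hierarchical outcomes with rare coexistence, sequencing
depths around 10^4 reads per community, invaders inoculated below 0.1%,
a cross-index misassignment rate near 0.1%, and invaders that nearly
displace the resident when they do invade.  Every generator takes an
explicit seed or Generator and is deterministic under it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demux import DESIGN_COLUMNS, SampleDesign
from .izmodel import CommunityModel
from .networks import (
    INVADES,
    MISSING,
    NO_INVASION,
    InhibitionMatrix,
    InvasionMatrix,
    PairCategory,
    StrainSet,
)

__all__ = [
    "random_invasion_matrix",
    "planted_hierarchy_matrix",
    "inhibition_from_hierarchy",
    "sample_community_model",
    "make_theorem_sampler",
    "make_pair_design",
    "simulate_competition_reads",
]

#: Default pair-category probabilities (bistable, hierarchical, coexistence).
#: Fixture default loosely mirroring a screen where roughly a third of
#: competitions end in invasion and mutual invasion is rare.
DEFAULT_CATEGORY_PROBS = (0.40, 0.55, 0.05)

#: Invader frequency after a successful invasion (resident nearly displaced).
DEFAULT_POST_INVASION_FREQ = 0.95


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _strain_labels(n: int) -> list[str]:
    return [f"s{i + 1}" for i in range(n)]


def random_invasion_matrix(
    n: int,
    rng: np.random.Generator | int,
    category_probs: tuple[float, float, float] = DEFAULT_CATEGORY_PROBS,
) -> tuple[InvasionMatrix, dict[tuple[str, str], PairCategory]]:
    """Invasion matrix with i.i.d. pair categories.

    ``category_probs`` gives (bistable, hierarchical, coexistence)
    probabilities; any remainder is the probability of an incomplete pair
    (one direction missing).  Hierarchical directions are uniform.
    Returns the matrix plus the ground-truth category per unordered pair.
    """
    pb, ph, pc = category_probs
    if min(pb, ph, pc) < 0 or pb + ph + pc > 1 + 1e-12:
        raise ValueError("category probabilities must be >= 0 and sum <= 1")
    rng = _rng(rng)
    labels = _strain_labels(n)
    entries = np.full((n, n), MISSING, dtype=np.int8)
    truth: dict[tuple[str, str], PairCategory] = {}
    for i, j in itertools.combinations(range(n), 2):
        u = rng.random()
        if u < pb:
            cat, (a, b) = PairCategory.BISTABLE, (NO_INVASION, NO_INVASION)
        elif u < pb + ph:
            cat = PairCategory.HIERARCHICAL
            a, b = (INVADES, NO_INVASION) if rng.random() < 0.5 else (NO_INVASION, INVADES)
        elif u < pb + ph + pc:
            cat, (a, b) = PairCategory.COEXISTENCE, (INVADES, INVADES)
        else:
            cat = PairCategory.INCOMPLETE
            a = MISSING
            b = INVADES if rng.random() < 0.5 else NO_INVASION
        entries[i, j], entries[j, i] = a, b
        truth[(labels[i], labels[j])] = cat
    return InvasionMatrix(StrainSet(labels), entries), truth


def planted_hierarchy_matrix(
    n: int,
    levels: int,
    rng: np.random.Generator | int,
    flip_prob: float = 0.0,
) -> tuple[InvasionMatrix, dict[str, int]]:
    """Invasion matrix generated from a planted strict hierarchy.

    Strains are spread round-robin over ``levels`` ranks; every
    cross-level pair carries a single invasion pointing down the
    hierarchy, flipped upward with probability ``flip_prob``; same-level
    pairs are bistable.  Returns the matrix and the planted levels.
    """
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    if not 1 <= levels <= n:
        raise ValueError("levels must be between 1 and n")
    rng = _rng(rng)
    labels = _strain_labels(n)
    planted = {labels[i]: levels - (i % levels) for i in range(n)}
    entries = np.full((n, n), MISSING, dtype=np.int8)
    for i, j in itertools.combinations(range(n), 2):
        hi, hj = planted[labels[i]], planted[labels[j]]
        if hi == hj:
            entries[i, j] = entries[j, i] = NO_INVASION
            continue
        up, down = (i, j) if hi > hj else (j, i)  # up = higher-level strain
        if rng.random() < flip_prob:
            up, down = down, up
        entries[up, down] = INVADES
        entries[down, up] = NO_INVASION
    return InvasionMatrix(StrainSet(labels), entries), planted


def inhibition_from_hierarchy(
    levels: dict[str, int],
    rng: np.random.Generator | int,
    p_down: float = 0.4,
    p_up: float = 0.05,
    p_equal: float | None = None,
) -> InhibitionMatrix:
    """Inhibition matrix biased to point down a hierarchy.

    An ordered pair from a higher to a lower level inhibits with
    ``p_down``; lower to higher with ``p_up``; equal levels with
    ``p_equal`` (default: mean of the two).
    """
    if not (0 <= p_down <= 1 and 0 <= p_up <= 1):
        raise ValueError("p_down and p_up must be in [0, 1]")
    if p_equal is None:
        p_equal = (p_down + p_up) / 2
    rng = _rng(rng)
    labels = list(levels)
    n = len(labels)
    entries = np.full((n, n), MISSING, dtype=np.int8)
    for i, j in itertools.permutations(range(n), 2):
        hi, hj = levels[labels[i]], levels[labels[j]]
        p = p_down if hi > hj else (p_up if hi < hj else p_equal)
        entries[i, j] = 1 if rng.random() < p else 0
    return InhibitionMatrix(StrainSet(labels), entries)


def sample_community_model(
    rng: np.random.Generator | int,
    n: int = 4,
    g_range: tuple[float, float] = (0.5, 1.5),
    k_density: float = 0.5,
    k_scale: float = 1.0,
    cyclic: bool = False,
    cyclic_strength: float = 1.0,
) -> CommunityModel:
    """Random community model for the inhibition-zone dynamics.

    Growth rates are uniform on ``g_range``; each off-diagonal inhibition
    K[j, i] is nonzero with probability ``k_density`` and, when nonzero,
    exponentially distributed with mean ``k_scale``.  With ``cyclic=True``
    an equal-growth rock-paper-scissors construction is returned instead
    (species i inhibits species i+1 with ``cyclic_strength``), which has a
    coexisting fixed point at the barycenter.
    """
    rng = _rng(rng)
    if cyclic:
        g = np.ones(n)
        K = np.zeros((n, n))
        for i in range(n):
            K[i, (i + 1) % n] = cyclic_strength
        return CommunityModel(g, K)
    g = rng.uniform(*g_range, size=n)
    K = np.where(rng.random((n, n)) < k_density, rng.exponential(k_scale, (n, n)), 0.0)
    np.fill_diagonal(K, 0.0)
    return CommunityModel(g, K)


def make_theorem_sampler(
    n_range: tuple[int, int] = (3, 5),
    cyclic_fraction: float = 0.2,
    g_range: tuple[float, float] = (0.5, 1.5),
    k_density: float = 0.5,
    k_scale: float = 1.0,
):
    """Sampler of mixed community models for theorem verification.

    Draws species counts uniformly from ``n_range``; a ``cyclic_fraction``
    of models use the equal-growth cyclic-inhibition construction so that
    the run is guaranteed to detect some coexisting sets rather than pass
    vacuously.
    """

    def sampler(rng: np.random.Generator) -> CommunityModel:
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        if rng.random() < cyclic_fraction:
            return sample_community_model(
                rng, n=n, cyclic=True, cyclic_strength=rng.uniform(0.5, 2.0)
            )
        return sample_community_model(
            rng, n=n, g_range=g_range, k_density=k_density, k_scale=k_scale
        )

    return sampler


def make_pair_design(
    strains: StrainSet | list[str],
    cycle: int = 3,
    inoc_freq: float = 0.001,
    i5_group_size: int = 24,
) -> SampleDesign:
    """Design table covering every ordered (invader, resident) pair once.

    Samples are packed into i5 groups of ``i5_group_size``; within a
    group each sample gets a distinct i7 index, and i7 labels repeat
    across groups (as with a physical dual-index plate layout).
    """
    if not isinstance(strains, StrainSet):
        strains = StrainSet(strains)
    rows = []
    k = 0
    for invader in strains:
        for resident in strains:
            if invader == resident:
                continue
            rows.append(
                {
                    "sample_id": f"c{k + 1:04d}",
                    "i5": f"i5_{k // i5_group_size + 1:02d}",
                    "i7": f"i7_{k % i5_group_size + 1:02d}",
                    "resident": resident,
                    "invader": invader,
                    "cycle": cycle,
                    "inoc_freq": inoc_freq,
                }
            )
            k += 1
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def simulate_competition_reads(
    truth: InvasionMatrix,
    design: SampleDesign,
    rng: np.random.Generator | int,
    depth: int = 10_000,
    epsilon: float = 0.001,
    post_invasion_freq: float = DEFAULT_POST_INVASION_FREQ,
) -> pd.DataFrame:
    """Read-count table for a design, given a ground-truth invasion matrix.

    Per sample the true final composition is set by the outcome: a
    successful invader reaches ``post_invasion_freq`` (resident nearly
    displaced); a failed invader is absent (below detection).  Reads are
    drawn multinomially at ``depth`` and then i7 hopping is applied: a
    read leaves its sample for a same-i5 partner with probability
    epsilon * N(i7_partner) / N_total, with N taken lane-wide from the
    pre-hop totals.
    """
    rng = _rng(rng)
    d = design.table
    strains = list(truth.strains.ids)
    counts = pd.DataFrame(0, index=d.index, columns=strains, dtype=np.int64)
    for sid in d.index:
        resident, invader = design.inoculated(sid)
        outcome = truth[invader, resident]
        if outcome == INVADES:
            freqs = {invader: post_invasion_freq, resident: 1 - post_invasion_freq}
        else:  # failed invasion (or missing ground truth): resident holds
            freqs = {resident: 1.0}
        p = np.array([freqs.get(s, 0.0) for s in strains])
        counts.loc[sid] = rng.multinomial(depth, p)
    if epsilon == 0:
        return counts
    # lane-wide i7 attraction weights from pre-hop totals
    totals = counts.sum(axis=1)
    w = totals.groupby(d["i7"]).sum()
    w = w / w.sum()
    hopped = counts.copy()
    for i5, group in d.groupby("i5"):
        ids = list(group.index)
        if len(ids) < 2:
            continue
        for sid in ids:
            dests = [t for t in ids if t != sid]
            p_dest = np.array([epsilon * w[str(d.loc[t, "i7"])] for t in dests])
            probs = np.append(p_dest, 1.0 - p_dest.sum())
            for s in strains:
                c = int(counts.at[sid, s])
                if c == 0:
                    continue
                alloc = rng.multinomial(c, probs)
                moved = alloc[:-1]
                if moved.any():
                    hopped.at[sid, s] -= int(moved.sum())
                    for t, mv in zip(dests, moved):
                        hopped.at[t, s] += int(mv)
    return hopped
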