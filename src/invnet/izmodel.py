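"""Mixed inhibition-zone population dynamics and the bistable-pair theorem.

Species i grows at intrinsic rate g_i, discounted exponentially by the
inhibition it receives from the rest of the community:

    f_i = g_i * exp(-sum_j K[j, i] * X_j)

where K[j, i] >= 0 is the inhibition-zone area species j projects onto
species i and X is the vector of relative abundances on the simplex.
Relative abundances follow replicator dynamics,

    dX_i/dt = X_i * (f_i - sum_j X_j f_j),

which conserve the simplex.  Setting the invader's abundance to zero and
the resident's to one yields the closed-form invasion condition: species i
invades resident j iff g_i * exp(-K[j, i]) > g_j (strictly).  A pair is
*bistable* when neither invades the other — each species excludes the
other whenever it is common.

The theorem checked by :func:`verify_bistable_pair_theorem`: in this model
(producers deriving no immediate benefit from inhibiting), any community
whose members coexist must contain at least one bistable pair.  Sketch:
the fastest grower must be inhibited by someone, else it unconditionally
wins; pairing it with its strongest inhibitor, lack of bistability would
make the fastest grower's minimum fitness exceed the inhibitor's maximum
fitness, excluding the inhibitor — a contradiction with coexistence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .networks import INVADES, MISSING, NO_INVASION, InvasionMatrix, StrainSet

__all__ = [
    "CommunityModel",
    "Trajectory",
    "CoexistenceReport",
    "TheoremReport",
    "fitness",
    "integrate_replicator",
    "pairwise_invades",
    "model_invasion_matrix",
    "find_coexisting_sets",
    "verify_bistable_pair_theorem",
]

_TIE_TOL = 1e-12
SIMPLEX_TOL = 1e-9


@dataclass
class CommunityModel:
    """Growth rates and inhibition-zone areas for n species.

    ``K[j, i]`` is the inhibition caused by species j acting on species i
    (dimensionless exponent scale); the diagonal is zero.
    """

    g: np.ndarray
    K: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.g)
        if self.K.shape != (n, n):
            raise ValueError(f"K shape {self.K.shape} does not match {n} species")
        if not (self.g > 0).all():
            raise ValueError("all growth rates must be > 0")
        if (self.K < 0).any():
            raise ValueError("inhibition-zone areas must be >= 0")
        if np.diag(self.K).any():
            raise ValueError("K must have a zero diagonal")
        if self.names is None:
            self.names = tuple(f"sp{i + 1}" for i in range(n))

    @property
    def n(self) -> int:
        return len(self.g)

    def to_dict(self) -> dict:
        return {"g": self.g.tolist(), "K": self.K.tolist(), "names": list(self.names)}

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        return cls(np.array(d["g"]), np.array(d["K"]), tuple(d.get("names") or ()) or None)


def _check_state(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x < -SIMPLEX_TOL).any() or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances must lie on the simplex, got sum {x.sum()}")
    return np.clip(x, 0.0, None)


def fitness(m: CommunityModel, x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Per-species fitness f_i = g_i * exp(-sum_j K[j, i] X_j)."""
    x = _check_state(x)
    return m.g * np.exp(-(m.K * x[:, None]).sum(axis=0))


@dataclass
class Trajectory:
    t: np.ndarray
    X: np.ndarray  # shape (len(t), n), renormalized onto the simplex
    max_simplex_drift: float  # largest |sum X - 1| before renormalization

    @property
    def final(self) -> np.ndarray:
        return self.X[-1]


def integrate_replicator(
    m: CommunityModel,
    x0: Sequence[float] | np.ndarray,
    horizon: float = 1000.0,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate dX_i/dt = X_i (f_i - mean fitness) to the horizon.

    Adaptive RK45 with the stated tolerances; output states are clipped at
    zero and renormalized onto the simplex, and the worst pre-correction
    drift is reported.  Species starting at exactly zero stay at zero.
    """
    x0 = _check_state(x0)

    def rhs(_t, x):
        f = m.g * np.exp(-(m.K * np.clip(x, 0.0, None)[:, None]).sum(axis=0))
        mean_f = float(x @ f)
        return x * (f - mean_f)

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(rhs, (0.0, horizon), x0, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    X = sol.y.T
    if not np.isfinite(X).all():
        raise RuntimeError("replicator integration produced non-finite abundances")
    drift = float(np.abs(X.sum(axis=1) - 1.0).max())
    X = np.clip(X, 0.0, None)
    X[:, x0 == 0.0] = 0.0
    X /= X.sum(axis=1, keepdims=True)
    return Trajectory(t=sol.t, X=X, max_simplex_drift=drift)


def pairwise_invades(m: CommunityModel, i: int, j: int) -> bool:
    """Closed-form invasibility: can species i, starting rare, invade an
    established resident j?  True iff g_i * exp(-K[j, i]) > g_j, with ties
    (within 1e-12) classified as non-invasion."""
    if i == j:
        raise ValueError("a species cannot invade itself")
    return m.g[i] * np.exp(-m.K[j, i]) > m.g[j] + _TIE_TOL


def model_invasion_matrix(m: CommunityModel) -> InvasionMatrix:
    """Ternary invasion matrix implied by the closed-form condition."""
    n = m.n
    entries = np.full((n, n), MISSING, dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if i != j:
                entries[i, j] = INVADES if pairwise_invades(m, i, j) else NO_INVASION
    return InvasionMatrix(StrainSet(m.names), entries)


@dataclass
class CoexistenceReport:
    """Persistent multi-species sets detected by forward integration."""

    sets: list[frozenset[int]]  # distinct persistent sets of size >= 2
    final_states: list[np.ndarray]  # one representative final state per set
    n_starts: int
    horizon: float
    persist_threshold: float
    max_simplex_drift: float = 0.0


def _persistent_set(
    m: CommunityModel,
    x0: np.ndarray,
    horizon: float,
    threshold: float,
    horizon_cap: float,
) -> tuple[frozenset[int], np.ndarray, float]:
    """Species above threshold at the horizon, with slow transients run out.

    Competitive exclusion between near-tied competitors can take arbitrarily
    long, so a fixed horizon would misread an unfinished exclusion as
    coexistence.  The integration is accepted once the state has converged
    (sup-norm change below 1e-6 over the second half of the run) or once no
    above-threshold species is monotonically declining (a persistent limit
    cycle); while some above-threshold species is still in monotone decline
    the horizon doubles, up to ``horizon_cap``.
    """
    t_horizon = horizon
    while True:
        traj = integrate_replicator(m, x0, horizon=t_horizon, n_points=101)
        final = traj.final
        second_half = traj.X[50:]  # t in [t_horizon/2, t_horizon]
        above = final >= threshold
        if t_horizon >= horizon_cap:
            break
        if np.abs(final - second_half[0]).max() < 1e-6:
            break  # stationary
        monotone_decline = (np.diff(second_half, axis=0) <= 1e-9).all(axis=0) & (
            final < second_half[0]
        )
        if not (above & monotone_decline).any():
            break  # no unfinished exclusion in sight (e.g. a cycle)
        t_horizon *= 2
    members = frozenset(np.flatnonzero(above).tolist())
    return members, final, traj.max_simplex_drift


def find_coexisting_sets(
    m: CommunityModel,
    n_starts: int = 20,
    horizon: float = 1000.0,
    persist_threshold: float = 1e-3,
    rng: np.random.Generator | int | None = None,
    horizon_cap_factor: float = 64.0,
) -> CoexistenceReport:
    """Detect coexisting communities by integrating from random interior
    starting points plus the barycenter.

    A species persists if its abundance is at least ``persist_threshold``
    at the horizon, after slow exclusion transients have been run out (see
    :func:`_persistent_set`; the horizon extends at most
    ``horizon_cap_factor`` times).  Persistent sets of size >= 2 are
    collected across starts; a persistent limit cycle counts as
    coexistence just like a fixed point.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = m.n
    starts = [np.full(n, 1.0 / n)]
    starts += [rng.dirichlet(np.ones(n)) for _ in range(n_starts)]
    seen: dict[frozenset[int], np.ndarray] = {}
    drift = 0.0
    cap = horizon * horizon_cap_factor
    for x0 in starts:
        persistent, final, d = _persistent_set(m, x0, horizon, persist_threshold, cap)
        drift = max(drift, d)
        # self-consistency: a coexisting community must sustain itself with
        # all outsiders at zero.  Restrict the model to the candidate set and
        # re-run from the renormalized final state; keep only members that
        # persist on their own face (iterating while the set shrinks).
        while len(persistent) >= 2:
            idx = sorted(persistent)
            sub = CommunityModel(m.g[idx], m.K[np.ix_(idx, idx)])
            x_sub = final[idx] / final[idx].sum()
            kept, final_sub, d = _persistent_set(
                sub, x_sub, horizon, persist_threshold, cap
            )
            drift = max(drift, d)
            members = frozenset(idx[k] for k in kept)
            if members == persistent:
                final = np.zeros(n)
                final[idx] = final_sub
                break
            persistent, final_kept = members, final_sub
            final = np.zeros(n)
            final[idx] = final_kept
        if len(persistent) >= 2 and persistent not in seen:
            seen[persistent] = final
    return CoexistenceReport(
        sets=list(seen),
        final_states=list(seen.values()),
        n_starts=n_starts,
        horizon=horizon,
        persist_threshold=persist_threshold,
        max_simplex_drift=drift,
    )


def bistable_pairs_in_set(m: CommunityModel, members: frozenset[int] | set[int]) -> list[tuple[int, int]]:
    """Pairs within ``members`` that are bistable by the closed form."""
    return [
        (i, j)
        for i, j in itertools.combinations(sorted(members), 2)
        if not pairwise_invades(m, i, j) and not pairwise_invades(m, j, i)
    ]


@dataclass
class TheoremReport:
    """Monte-Carlo check that every coexisting set has a bistable pair."""

    n_models: int
    n_sets: int
    min_bistable_pairs: int | None  # min over detected sets; None if no sets
    counterexamples: list[dict]  # model dict + offending set, verbatim
    per_model: list[dict]

    @property
    def consistent(self) -> bool:
        return not self.counterexamples


def verify_bistable_pair_theorem(
    sampler: Callable[[np.random.Generator], CommunityModel],
    n_models: int,
    rng: np.random.Generator | int | None = None,
    n_starts: int = 5,
    horizon: float = 1000.0,
    persist_threshold: float = 1e-3,
) -> TheoremReport:
    """Sample community models, detect coexisting sets by integration, and
    count closed-form bistable pairs inside each detected set.

    Any detected set of size >= 2 with zero bistable pairs is recorded as a
    counterexample with its model parameters verbatim.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    per_model = []
    counterexamples = []
    mins: list[int] = []
    for k in range(n_models):
        m = sampler(rng)
        report = find_coexisting_sets(
            m,
            n_starts=n_starts,
            horizon=horizon,
            persist_threshold=persist_threshold,
            rng=rng,
        )
        counts = [len(bistable_pairs_in_set(m, s)) for s in report.sets]
        mins.extend(counts)
        for s, c in zip(report.sets, counts):
            if c == 0:
                counterexamples.append({"model": m.to_dict(), "set": sorted(s)})
        per_model.append(
            {
                "model_index": k,
                "n_species": m.n,
                "coexisting_sets": [sorted(s) for s in report.sets],
                "bistable_pair_counts": counts,
            }
        )
    return TheoremReport(
        n_models=n_models,
        n_sets=len(mins),
        min_bistable_pairs=(min(mins) if mins else None),
        counterexamples=counterexamples,
        per_model=per_model,
    )
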