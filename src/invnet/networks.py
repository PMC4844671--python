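"""Core data types for invasion and inhibition networks.

An *invasion matrix* records, for an ordered pair of strains (invader,
resident), whether the invader — inoculated at low abundance against an
established resident — rose to at least 1% of the community over serial
propagation.  Entries are ternary: ``INVADES``, ``NO_INVASION`` or
``MISSING`` (the experiment for that ordered pair failed or was marked
defective).  An *inhibition matrix* records the binary outcome of a
cross-streak assay: whether the row strain prevents sporulation of the
column strain within >= 1 mm.

Both matrices share the convention rows = actor (invader / inhibitor),
columns = target (resident / inhibited strain).  The diagonal is MISSING by
construction and excluded from every statistic.

Each unordered pair of strains falls into one of four categories based on
its two ordered outcomes:

* ``BISTABLE`` — neither strain invades the other ("survival of the
  common": whichever strain is abundant persists),
* ``HIERARCHICAL`` — exactly one direction invades,
* ``COEXISTENCE`` — mutual invasion (each strain increases when rare),
* ``INCOMPLETE`` — at least one direction is missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "INVADES",
    "NO_INVASION",
    "INHIBITS",
    "NO_INHIBITION",
    "MISSING",
    "PairCategory",
    "PairOutcome",
    "StrainSet",
    "TernaryMatrix",
    "InvasionMatrix",
    "InhibitionMatrix",
    "classify_pair",
    "outcome_counts",
    "bistability_degree",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

# Cell states, stored as int8. INVADES/INHIBITS share the positive code so
# that invasion and inhibition matrices use one array layout.
INVADES: int = 1
NO_INVASION: int = 0
INHIBITS: int = 1
NO_INHIBITION: int = 0
MISSING: int = -1

_TOKEN_TO_STATE = {"1": 1, "0": 0, "na": MISSING, "nan": MISSING}
_STATE_TO_TOKEN = {1: "1", 0: "0", MISSING: "NA"}


class PairCategory(enum.Enum):
    """Category of an unordered strain pair in the invasion network."""

    BISTABLE = "bistable"
    HIERARCHICAL = "hierarchical"
    COEXISTENCE = "coexistence"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class PairOutcome:
    """Classification of one unordered pair.

    ``direction`` is the invading strain's label for HIERARCHICAL pairs and
    ``None`` otherwise.
    """

    category: PairCategory
    direction: str | None = None


class StrainSet:
    """Ordered collection of unique strain labels shared by all matrices.

    Replicate isolates (e.g. "1a" and "1b") are ordinary distinct labels;
    no merging is performed.
    """

    def __init__(self, ids: Sequence[str], metadata: Mapping[str, str] | None = None):
        ids = [str(s) for s in ids]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate strain labels: {dupes}")
        self.ids: tuple[str, ...] = tuple(ids)
        self.metadata: dict[str, str] = dict(metadata or {})
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StrainSet) and self.ids == other.ids

    def __repr__(self) -> str:
        return f"StrainSet({list(self.ids)!r})"

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown strain label: {label!r}") from None


class TernaryMatrix:
    """Square matrix of ternary states over a StrainSet.

    Base class for :class:`InvasionMatrix` and :class:`InhibitionMatrix`;
    rows are the acting strain, columns the target.  The diagonal is forced
    to MISSING.
    """

    _positive_name = "1"

    def __init__(self, strains: StrainSet | Sequence[str], entries: np.ndarray):
        if not isinstance(strains, StrainSet):
            strains = StrainSet(strains)
        entries = np.asarray(entries, dtype=np.int8)
        n = len(strains)
        if entries.shape != (n, n):
            raise ValueError(
                f"entries shape {entries.shape} does not match {n} strains"
            )
        bad = ~np.isin(entries, (INVADES, NO_INVASION, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal state {entries[i, j]} at ({strains.ids[i]}, {strains.ids[j]})"
            )
        entries = entries.copy()
        np.fill_diagonal(entries, MISSING)
        self.strains = strains
        self.entries = entries

    @property
    def n(self) -> int:
        return len(self.strains)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.entries[self.strains.index(a), self.strains.index(b)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TernaryMatrix)
            and self.strains == other.strains
            and np.array_equal(self.entries, other.entries)
        )

    def complete_pair_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of unordered pairs (upper triangle mirrored)
        where both ordered entries are observed."""
        obs = self.entries != MISSING
        return obs & obs.T


class InvasionMatrix(TernaryMatrix):
    """Directed pairwise invasion outcomes: entry (i, j) says whether strain
    i, starting rare, invades an established resident j."""

    _positive_name = "invasion"


class InhibitionMatrix(TernaryMatrix):
    """Directed inhibition outcomes from the cross-streak assay: entry
    (i, j) says whether strain i inhibits sporulation of strain j."""

    _positive_name = "inhibition"


def classify_pair(inv: InvasionMatrix, a: str, b: str) -> PairOutcome:
    """Classify the unordered pair {a, b} from its two directed outcomes.

    Bistable if neither invades, hierarchical if exactly one invades (with
    ``direction`` naming the invader), coexistence if both invade, and
    incomplete if either direction is missing.
    """
    if a == b:
        raise ValueError(f"cannot classify a strain against itself: {a!r}")
    ab = inv[a, b]
    ba = inv[b, a]
    if ab == MISSING or ba == MISSING:
        return PairOutcome(PairCategory.INCOMPLETE)
    if ab == INVADES and ba == INVADES:
        return PairOutcome(PairCategory.COEXISTENCE)
    if ab == NO_INVASION and ba == NO_INVASION:
        return PairOutcome(PairCategory.BISTABLE)
    return PairOutcome(PairCategory.HIERARCHICAL, direction=a if ab == INVADES else b)


def outcome_counts(inv: InvasionMatrix) -> dict[PairCategory, int]:
    """Count pair categories over all n(n-1)/2 unordered pairs."""
    counts = {c: 0 for c in PairCategory}
    ids = inv.strains.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            counts[classify_pair(inv, ids[i], ids[j]).category] += 1
    return counts


def bistability_degree(inv: InvasionMatrix, s: str) -> int:
    """Number of partners with which strain ``s`` forms a bistable pair."""
    inv.strains.index(s)  # raise early on unknown label
    return sum(
        1
        for t in inv.strains
        if t != s and classify_pair(inv, s, t).category is PairCategory.BISTABLE
    )


def bistability_degrees(inv: InvasionMatrix) -> dict[str, int]:
    """Bistability degree for every strain."""
    return {s: bistability_degree(inv, s) for s in inv.strains}


# --------------------------------------------------------------------------
# TSV I/O
#
# Format: header row "strain<TAB>label1<TAB>label2...", one row per acting
# strain, cells in {1, 0, NA}. Rows = invader/inhibitor, columns =
# resident/target.

def write_matrix_tsv(m: TernaryMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = ["strain\t" + "\t".join(m.strains.ids)]
    for i, s in enumerate(m.strains.ids):
        cells = [_STATE_TO_TOKEN[int(v)] for v in m.entries[i]]
        lines.append(s + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path: str | Path, kind: str = "invasion") -> TernaryMatrix:
    """Read a square ternary matrix from TSV.

    ``kind`` selects the returned type: "invasion" or "inhibition".
    Cell tokens 1 / 0 / NA (case-insensitive "na"/"nan" accepted).
    """
    cls: type[TernaryMatrix]
    if kind == "invasion":
        cls = InvasionMatrix
    elif kind == "inhibition":
        cls = InhibitionMatrix
    else:
        raise ValueError(f"kind must be 'invasion' or 'inhibition', got {kind!r}")

    path = Path(path)
    rows = [line.split("\t") for line in path.read_text().splitlines() if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0][1:]]
    n = len(header)
    if len(rows) - 1 != n:
        raise ValueError(f"{path}: {len(rows) - 1} data rows but {n} columns — not square")
    labels = []
    entries = np.empty((n, n), dtype=np.int8)
    for r, row in enumerate(rows[1:]):
        if len(row) != n + 1:
            raise ValueError(f"{path}: row {row[0]!r} has {len(row) - 1} cells, expected {n}")
        labels.append(row[0].strip())
        for c, tok in enumerate(row[1:]):
            try:
                entries[r, c] = _TOKEN_TO_STATE[tok.strip().lower()]
            except KeyError:
                raise ValueError(
                    f"{path}: illegal cell {tok!r} at row {row[0]!r}, column {header[c]!r}"
                ) from None
    if labels != header:
        raise ValueError(f"{path}: row labels {labels} do not match header {header}")
    try:
        strains = StrainSet(labels)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None
    return cls(strains, entries)
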