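import itertools

import numpy as np
import pytest

from invnet.networks import (
    INVADES,
    MISSING,
    NO_INVASION,
    InhibitionMatrix,
    InvasionMatrix,
    StrainSet,
)


def make_invasion(entries, labels=None) -> InvasionMatrix:
    entries = np.asarray(entries, dtype=np.int8)
    labels = labels or [chr(ord("A") + i) for i in range(len(entries))]
    return InvasionMatrix(StrainSet(labels), entries)


def make_inhibition(entries, labels=None) -> InhibitionMatrix:
    entries = np.asarray(entries, dtype=np.int8)
    labels = labels or [chr(ord("A") + i) for i in range(len(entries))]
    return InhibitionMatrix(StrainSet(labels), entries)


def all_bistable(n: int) -> InvasionMatrix:
    e = np.zeros((n, n), dtype=np.int8)
    np.fill_diagonal(e, MISSING)
    return make_invasion(e)


def transitive_chain(n: int) -> InvasionMatrix:
    """Complete transitive hierarchy: strain i invades every strain j > i."""
    e = np.zeros((n, n), dtype=np.int8)
    for i, j in itertools.combinations(range(n), 2):
        e[i, j] = INVADES
        e[j, i] = NO_INVASION
    np.fill_diagonal(e, MISSING)
    return make_invasion(e)


@pytest.fixture
def chain3() -> InvasionMatrix:
    return transitive_chain(3)
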