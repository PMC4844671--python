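"""Cross-index background subtraction and invasion calling.

Communities are demultiplexed by a dual (i5, i7) index pair.  A small
fraction of reads acquire a wrong i7 index ("index hopping"), so a sample
receives stray reads from other samples sharing its i5 index.  The
background model: a read hops into index i7 with probability

    p(i7) = epsilon * N(i7) / sum_k N(k)

where N(i7) is the lane-wide total of reads carrying i7 and epsilon is the
global misassignment rate (about 0.1% in dual-indexed amplicon runs of the
kind modelled here).  The expected background of strain s in sample
(i5, i7) is p(i7) times the total reads of s in other samples with the
same i5.  epsilon is fitted by the method of moments on cells whose strain
is known to be absent, and a strain is called an invader only if, after
subtracting the expected background, it has increased in frequency and
makes up at least 1% of the community.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import INVADES, MISSING, NO_INVASION, InvasionMatrix, StrainSet

__all__ = [
    "SampleDesign",
    "BackgroundModel",
    "read_counts_csv",
    "write_counts_csv",
    "expected_background",
    "fit_background",
    "call_invasion",
    "invasion_matrix_from_calls",
]

DESIGN_COLUMNS = ["sample_id", "i5", "i7", "resident", "invader", "cycle", "inoc_freq"]


@dataclass
class SampleDesign:
    """Experiment design: one row per sequenced community.

    Columns: sample_id, i5, i7, resident, invader, cycle, inoc_freq
    (initial invader frequency).  (i5, i7) pairs must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        if t.duplicated(subset=["i5", "i7"]).any():
            raise ValueError("duplicate (i5, i7) index pair in design")
        self.table = t.set_index("sample_id", drop=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, dtype={"i5": str, "i7": str, "sample_id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def inoculated(self, sample_id: str) -> tuple[str, str]:
        row = self.table.loc[sample_id]
        return str(row["resident"]), str(row["invader"])


@dataclass
class BackgroundModel:
    """Fitted cross-index contamination model.

    epsilon: global fraction of reads that hop to a wrong i7 index.
    i7_weight: attraction per i7 index, N(i7) / sum N — hops land on an
        index in proportion to how many reads legitimately carry it.
    """

    epsilon: float
    i7_weight: dict[str, float]
    residuals: pd.DataFrame | None = None

    def p_hop_into(self, i7: str) -> float:
        return self.epsilon * self.i7_weight.get(str(i7), 0.0)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format counts CSV (sample_id,i5,i7,strain,count) into a
    sample x strain count table (samples indexed by sample_id)."""
    long = pd.read_csv(path, dtype={"i5": str, "i7": str, "sample_id": str, "strain": str})
    wide = (
        long.pivot_table(index="sample_id", columns="strain", values="count",
                         aggfunc="sum", fill_value=0)
        .astype(int)
    )
    wide.columns.name = None
    return wide

def write_counts_csv(counts: pd.DataFrame, design: SampleDesign, path: str | Path) -> None:
    long = counts.stack().rename("count").reset_index()
    long.columns = ["sample_id", "strain", "count"]
    idx = design.table[["i5", "i7"]]
    long = long.join(idx, on="sample_id")
    long[["sample_id", "i5", "i7", "strain", "count"]].to_csv(path, index=False)


def _aligned(design: SampleDesign, counts: pd.DataFrame) -> pd.DataFrame:
    unknown = counts.index.difference(design.table.index)
    if len(unknown):
        raise ValueError(f"count rows without a design entry: {list(unknown)[:5]}")
    return counts.reindex(design.table.index, fill_value=0)


def _i7_weights(design: SampleDesign, counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=1)
    by_i7 = totals.groupby(design.table["i7"]).sum()
    return by_i7 / by_i7.sum()


def _background_at_unit_rate(
    design: SampleDesign, counts: pd.DataFrame, w: pd.Series
) -> pd.DataFrame:
    """Expected background per (sample, strain) at epsilon = 1: the i7
    attraction weight times the summed counts of same-i5 partners."""
    counts = _aligned(design, counts)
    d = design.table
    bg = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for i5, group in d.groupby("i5"):
        ids = group.index
        group_sum = counts.loc[ids].sum(axis=0)
        for sid in ids:
            partners = group_sum - counts.loc[sid]  # same i5, different i7
            bg.loc[sid] = w[str(d.loc[sid, "i7"])] * partners
    return bg


def expected_background(
    design: SampleDesign, counts: pd.DataFrame, model: BackgroundModel
) -> pd.DataFrame:
    """Expected stray reads per (sample, strain) under the fitted model.

    Samples that share their i5 index with no other sample have zero
    background (no hop sources)."""
    w = pd.Series(model.i7_weight, dtype=float)
    return model.epsilon * _background_at_unit_rate(design, counts, w)


def fit_background(
    design: SampleDesign,
    counts: pd.DataFrame,
    absent: dict[str, list[str]] | None = None,
) -> BackgroundModel:
    """Method-of-moments fit of the misassignment rate epsilon.

    ``absent`` maps sample_id -> strains known to be absent from that
    community; by default every strain in the count table that was not
    inoculated (neither resident nor invader, per the design) is treated
    as known absent.  epsilon is the ratio of total observed reads in
    known-absent cells to the total background predicted for those cells
    at epsilon = 1.
    """
    counts = _aligned(design, counts)
    if absent is None:
        absent = {}
        for sid in counts.index:
            inoc = set(design.inoculated(sid))
            absent[sid] = [s for s in counts.columns if s not in inoc]
    cells = [(sid, s) for sid, strains in absent.items() for s in strains]
    if not cells:
        raise ValueError("no known-absent (sample, strain) cells: cannot fit epsilon")
    w = _i7_weights(design, counts)
    unit = _background_at_unit_rate(design, counts, w)
    obs_total = float(sum(counts.at[sid, s] for sid, s in cells))
    unit_total = float(sum(unit.at[sid, s] for sid, s in cells))
    if unit_total == 0:
        raise ValueError("predicted background is zero in every known-absent cell")
    eps = obs_total / unit_total
    resid = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "strain": s,
                "observed": counts.at[sid, s],
                "expected": eps * unit.at[sid, s],
            }
            for sid, s in cells
        ]
    )
    resid["residual"] = resid["observed"] - resid["expected"]
    return BackgroundModel(epsilon=eps, i7_weight=w.to_dict(), residuals=resid)


INVADED = "INVADED"
NOT_INVADED = "NOT_INVADED"
DEFECTIVE = "DEFECTIVE"


def call_invasion(
    design: SampleDesign,
    counts: pd.DataFrame,
    model: BackgroundModel,
    threshold: float = 0.01,
    defect_factor: float = 2.0,
    detection_z: float = 4.0,
) -> pd.DataFrame:
    """Call invasion per sample after background subtraction.

    For each community the invader's reads are compared with the expected
    cross-index background b.  Reads within the background's sampling
    band — at most b + detection_z * sqrt(b), the Poisson fluctuation
    expected of pure hopping — are below the detection limit
    (non-invasion).  Reads detectably above background but still under
    ``defect_factor`` times it are too marginal to call and the community
    is marked DEFECTIVE.  Otherwise frequencies are computed from
    background-subtracted counts over the inoculated strains, and the
    invader must both exceed its inoculation frequency and reach
    ``threshold`` (default 1%) of the community to be called INVADED.
    """
    counts = _aligned(design, counts)
    bg = expected_background(design, counts, model)
    rows = []
    for sid in counts.index:
        resident, invader = design.inoculated(sid)
        for strain in (resident, invader):
            if strain not in counts.columns:
                raise ValueError(f"strain {strain!r} missing from count table")
        o_inv = float(counts.at[sid, invader])
        b_inv = float(bg.at[sid, invader])
        detection_limit = b_inv + detection_z * np.sqrt(b_inv)
        sub = {
            s: max(0.0, float(counts.at[sid, s]) - float(bg.at[sid, s]))
            for s in (resident, invader)
        }
        total = sum(sub.values())
        inoc_freq = float(design.table.at[sid, "inoc_freq"])
        if total == 0:
            call, freq = DEFECTIVE, np.nan
        elif o_inv <= detection_limit or o_inv == 0:
            call, freq = NOT_INVADED, 0.0
        elif o_inv < defect_factor * b_inv:
            call, freq = DEFECTIVE, np.nan
        else:
            freq = sub[invader] / total
            call = INVADED if (freq >= threshold and freq > inoc_freq) else NOT_INVADED
        rows.append(
            {
                "sample_id": sid,
                "invader": invader,
                "resident": resident,
                "cycle": design.table.at[sid, "cycle"],
                "observed": o_inv,
                "background": b_inv,
                "frequency": freq,
                "call": call,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def invasion_matrix_from_calls(
    calls: pd.DataFrame,
    strains: StrainSet | list[str] | None = None,
    cycle: int | None = None,
) -> InvasionMatrix:
    """Assemble a ternary invasion matrix from per-sample calls.

    Uses the final propagation cycle unless ``cycle`` is given; expects
    exactly one sample per ordered (invader, resident) pair at that cycle
    (duplicates are refused — resolve replicates upstream).  DEFECTIVE
    calls become MISSING entries.
    """
    if cycle is None:
        cycle = int(calls["cycle"].max())
    final = calls[calls["cycle"] == cycle]
    if final.duplicated(subset=["invader", "resident"]).any():
        dupes = final[final.duplicated(subset=["invader", "resident"], keep=False)]
        raise ValueError(
            "multiple samples for ordered pair(s) "
            f"{sorted(set(zip(dupes['invader'], dupes['resident'])))}; "
            "apply a consensus policy before assembling the matrix"
        )
    if strains is None:
        strains = sorted(set(final["invader"]) | set(final["resident"]))
    if not isinstance(strains, StrainSet):
        strains = StrainSet(strains)
    n = len(strains)
    entries = np.full((n, n), MISSING, dtype=np.int8)
    state = {INVADED: INVADES, NOT_INVADED: NO_INVASION, DEFECTIVE: MISSING}
    for _, row in final.iterrows():
        i = strains.index(str(row["invader"]))
        j = strains.index(str(row["resident"]))
        entries[i, j] = state[row["call"]]
    return InvasionMatrix(strains, entries)
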