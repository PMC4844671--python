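"""Index-hopping background model, epsilon fitting and invasion calling."""

import numpy as np
import pandas as pd
import pytest

from invnet.demux import (
    DEFECTIVE,
    INVADED,
    NOT_INVADED,
    BackgroundModel,
    SampleDesign,
    call_invasion,
    expected_background,
    fit_background,
    invasion_matrix_from_calls,
    read_counts_csv,
    write_counts_csv,
)
from invnet.networks import MISSING, NO_INVASION
from invnet.synthetic_data import make_pair_design, random_invasion_matrix, simulate_competition_reads


def _design(rows):
    return SampleDesign(pd.DataFrame(rows))


def _two_sample_toy():
    """Two samples sharing an i5 index, equal totals."""
    design = _design(
        [
            dict(sample_id="s1", i5="A", i7="x", resident="r1", invader="v1",
                 cycle=3, inoc_freq=0.001),
            dict(sample_id="s2", i5="A", i7="y", resident="r2", invader="v2",
                 cycle=3, inoc_freq=0.001),
        ]
    )
    counts = pd.DataFrame(
        {"r1": [10_000, 0], "r2": [0, 10_000]}, index=["s1", "s2"]
    )
    return design, counts


def test_background_zero_when_epsilon_zero():
    design, counts = _two_sample_toy()
    model = BackgroundModel(epsilon=0.0, i7_weight={"x": 0.5, "y": 0.5})
    assert (expected_background(design, counts, model) == 0).all().all()


def test_background_zero_without_i5_partner():
    design = _design(
        [
            dict(sample_id="s1", i5="A", i7="x", resident="r1", invader="v1",
                 cycle=3, inoc_freq=0.001),
            dict(sample_id="s2", i5="B", i7="y", resident="r2", invader="v2",
                 cycle=3, inoc_freq=0.001),
        ]
    )
    counts = pd.DataFrame({"r1": [9000, 0], "r2": [0, 11000]}, index=["s1", "s2"])
    model = BackgroundModel(epsilon=0.001, i7_weight={"x": 0.45, "y": 0.55})
    assert (expected_background(design, counts, model) == 0).all().all()


def test_background_two_sample_reference_value():
    # equal i7 totals: p(i7) = 0.001 * 0.5; partner holds 10,000 reads of r2,
    # so sample s1 expects 5 stray r2 reads
    design, counts = _two_sample_toy()
    model = BackgroundModel(epsilon=0.001, i7_weight={"x": 0.5, "y": 0.5})
    bg = expected_background(design, counts, model)
    assert bg.at["s1", "r2"] == pytest.approx(5.0)
    assert bg.at["s2", "r1"] == pytest.approx(5.0)
    assert bg.at["s1", "r1"] == pytest.approx(0.0)


def test_background_linear_in_epsilon_and_counts():
    design, counts = _two_sample_toy()
    w = {"x": 0.5, "y": 0.5}
    b1 = expected_background(design, counts, BackgroundModel(0.001, w))
    b2 = expected_background(design, counts, BackgroundModel(0.002, w))
    b3 = expected_background(design, counts * 2, BackgroundModel(0.001, w))
    assert np.allclose(2 * b1.values, b2.values)
    assert np.allclose(2 * b1.values, b3.values)


class TestFitBackground:
    def test_contamination_free_table_gives_zero(self):
        design, counts = _two_sample_toy()
        model = fit_background(design, counts)
        assert model.epsilon == 0.0

    def test_refuses_without_absent_cells(self):
        design, counts = _two_sample_toy()
        with pytest.raises(ValueError, match="absent"):
            fit_background(design, counts, absent={})

    def test_recovers_generating_rate(self):
        rng = np.random.default_rng(0)
        inv, _ = random_invasion_matrix(7, rng=rng)
        design = make_pair_design(inv.strains, i5_group_size=12)
        reads = simulate_competition_reads(
            inv, design, rng=rng, depth=10_000, epsilon=0.001
        )
        model = fit_background(design, reads)
        assert model.epsilon == pytest.approx(0.001, rel=0.2)
        assert model.residuals is not None and len(model.residuals) > 0


class TestCallInvasion:
    def _single(self, n_inv, n_res, bg_weight=0.5, partner=None, inoc=0.001,
                threshold=0.01, defect_factor=2.0):
        rows = [
            dict(sample_id="s1", i5="A", i7="x", resident="R", invader="V",
                 cycle=3, inoc_freq=inoc),
            dict(sample_id="s2", i5="A", i7="y", resident="V", invader="R",
                 cycle=3, inoc_freq=inoc),
        ]
        design = _design(rows)
        partner = partner or {"V": 0, "R": 20_000}
        counts = pd.DataFrame(
            {"V": [n_inv, partner["V"]], "R": [n_res, partner["R"]]},
            index=["s1", "s2"],
        )
        model = BackgroundModel(epsilon=0.001, i7_weight={"x": bg_weight, "y": 1 - bg_weight})
        return call_invasion(design, counts, model, threshold=threshold,
                             defect_factor=defect_factor).loc["s1"]

    def test_five_percent_invader_called(self):
        row = self._single(500, 9500, partner={"V": 0, "R": 0})
        assert row["call"] == INVADED
        assert row["frequency"] == pytest.approx(0.05)

    def test_half_percent_not_called(self):
        row = self._single(50, 9950, partner={"V": 0, "R": 0})
        assert row["call"] == NOT_INVADED

    def test_marginal_signal_marked_defective(self):
        # background 100 reads, observed 150: detectably above background
        # (beyond the Poisson band) yet under twice its level
        row = self._single(150, 9850, partner={"V": 200_000, "R": 0})
        assert row["background"] == pytest.approx(100.0)
        assert row["call"] == DEFECTIVE

    def test_reads_within_background_band_are_non_invasions(self):
        row = self._single(101, 9899, partner={"V": 200_000, "R": 0})
        assert row["call"] == NOT_INVADED

    def test_calls_monotone_in_threshold(self):
        for n_inv in (0, 30, 120, 400, 2000):
            lo = self._single(n_inv, 10_000 - n_inv, partner={"V": 0, "R": 0},
                              threshold=0.005)
            hi = self._single(n_inv, 10_000 - n_inv, partner={"V": 0, "R": 0},
                              threshold=0.03)
            if hi["call"] == INVADED:
                assert lo["call"] == INVADED

    def test_must_increase_above_inoculation_frequency(self):
        row = self._single(150, 9850, partner={"V": 0, "R": 0}, inoc=0.02)
        assert row["call"] == NOT_INVADED  # 1.5% > threshold but below inoculum


class TestMatrixFromCalls:
    def _calls(self, call_by_pair, cycle=3):
        rows = [
            dict(sample_id=f"s{k}", invader=i, resident=r, cycle=cycle,
                 observed=0, background=0, frequency=0.0, call=c)
            for k, ((i, r), c) in enumerate(call_by_pair.items())
        ]
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def test_all_not_invaded_gives_all_bistable(self):
        pairs = {(a, b): NOT_INVADED for a in "ABC" for b in "ABC" if a != b}
        inv = invasion_matrix_from_calls(self._calls(pairs))
        assert (inv.entries[~np.eye(3, dtype=bool)] == NO_INVASION).all()

    def test_defective_becomes_missing(self):
        pairs = {(a, b): NOT_INVADED for a in "ABC" for b in "ABC" if a != b}
        pairs[("A", "B")] = DEFECTIVE
        inv = invasion_matrix_from_calls(self._calls(pairs))
        assert inv["A", "B"] == MISSING
        assert int((inv.entries == MISSING).sum()) == 3 + 1  # diagonal + one call

    def test_duplicate_pair_refused(self):
        calls = self._calls({("A", "B"): NOT_INVADED, ("B", "A"): NOT_INVADED})
        dup = pd.concat([calls, calls.iloc[[0]].assign(sample_id="dup")])
        with pytest.raises(ValueError, match="consensus"):
            invasion_matrix_from_calls(dup)


def test_counts_csv_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    inv, _ = random_invasion_matrix(4, rng=rng)
    design = make_pair_design(inv.strains, i5_group_size=6)
    reads = simulate_competition_reads(inv, design, rng=rng, depth=1000, epsilon=0.0)
    p = tmp_path / "counts.csv"
    write_counts_csv(reads, design, p)
    back = read_counts_csv(p)
    pd.testing.assert_frame_equal(
        back.sort_index(), reads.sort_index().astype(int), check_names=False
    )


def test_end_to_end_recovers_ground_truth_matrix():
    rng = np.random.default_rng(11)
    inv, _ = random_invasion_matrix(6, rng=rng)
    design = make_pair_design(inv.strains, i5_group_size=10)
    reads = simulate_competition_reads(inv, design, rng=rng, depth=100_000, epsilon=0.001)
    model = fit_background(design, reads)
    calls = call_invasion(design, reads, model)
    recovered = invasion_matrix_from_calls(calls, strains=inv.strains)
    assert recovered == inv
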