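"""ELEFAN: binning, restructuring, curve scoring, GA search, bootstrap."""

import datetime as dt
import math

import numpy as np
import pytest

from fishgrowth import (
    ELEFANParams,
    GASettings,
    GrowthParams,
    LFQSample,
    bin_lengths,
    bootstrap_elefan,
    ga_optimize,
    restructure,
    score_growth_curve,
    simulate_length_frequency,
)
from fishgrowth.elefan import LFQMatrix, date_to_decimal_year

from conftest import ELEFAN_TRUTH


def _matrix(counts, dates=None, bin_width=10.0):
    counts = np.atleast_2d(np.asarray(counts))
    if dates is None:
        dates = tuple(dt.date(2020, 1, 1) + dt.timedelta(days=200 * i)
                      for i in range(counts.shape[0]))
    mids = (np.arange(counts.shape[1]) + 0.5) * bin_width
    return LFQMatrix(dates=tuple(dates), bin_mids=mids, counts=counts,
                     bin_width=bin_width)


class TestBinning:
    def test_bin_convention_lower_inclusive(self):
        s = [LFQSample(date=dt.date(2020, 5, 1), lengths=np.array([154.0]))]
        lfq = bin_lengths(s, 10.0)
        assert lfq.counts[0, np.where(lfq.bin_mids == 155.0)[0][0]] == 1

    def test_total_count_conserved(self):
        samples = simulate_length_frequency(ELEFAN_TRUTH, seed=2)
        lfq = bin_lengths(samples, 10.0)
        assert lfq.counts.sum() == sum(len(s.lengths) for s in samples)
        assert len(lfq.dates) == 25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_lengths([], 10.0)


class TestRestructure:
    def test_uniform_counts_score_zero(self):
        r = restructure(_matrix(np.full(12, 7)), ma_window=5)
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_hand_computed_toy_column(self):
        """7-bin column [0, 0, 1, 5, 1, 0, 0], MA window 5, worked by hand.

        MA (zero-padded): [.2, 1.2, 1.4, 1.4, 1.4, 1.2, .2]
        count/MA - 1:     [-1, -1, -2/7, 18/7, -2/7, -1, -1]
        de-emphasis of the single positive bin: its 4 neighbours hold one
        zero-count bin on each side -> factor 1 - 2/4 = 1/2 -> 9/7.
        negatives rescaled so the sums cancel: factor (9/7)/(32/7) = 9/32.
        """
        r = restructure(_matrix([0, 0, 1, 5, 1, 0, 0]), ma_window=5)
        v = r.values[0]
        assert v[3] == pytest.approx(9 / 7)
        assert v[2] == pytest.approx(-(2 / 7) * (9 / 32))
        assert v[0] == pytest.approx(-1.0 * (9 / 32))
        assert v.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_sum_and_floor_on_random_matrices(self, rng):
        for _ in range(25):
            counts = rng.poisson(2.0, size=(3, 14))
            r = restructure(_matrix(counts), ma_window=5)
            assert np.all(r.values >= -1.0 - 1e-12)
            for row, c in zip(r.values, counts):
                if (row > 0).any():
                    assert abs(row.sum()) < 1e-9

    def test_all_zero_column_stays_zero(self):
        counts = np.vstack([np.zeros(10, dtype=int), [0, 0, 3, 9, 3, 0, 0, 0, 1, 0]])
        r = restructure(_matrix(counts), ma_window=5)
        np.testing.assert_allclose(r.values[0], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            restructure(_matrix(np.ones(8)), ma_window=4)


def brute_force_score(r, p):
    """Independent traversal oracle: plain loops and explicit sets."""
    values = r.values
    nd, nb = values.shape
    # peaks by scanning runs
    peak_of = {}
    peak_sum = []
    for d in range(nd):
        run = None
        for b in range(nb):
            if values[d, b] > 0:
                if run is None:
                    run = len(peak_sum)
                    peak_sum.append(0.0)
                peak_of[(d, b)] = run
                peak_sum[run] += values[d, b]
            else:
                run = None
    asp = sum(peak_sum)
    # curve family traversal
    t = [date_to_decimal_year(d) for d in r.dates]
    lo = r.bin_mids[0] - r.bin_width / 2
    hi = r.bin_mids[-1] + r.bin_width / 2
    max_len = min(hi, 0.95 * p.l_inf)
    a_max = min(-math.log(1 - max_len / p.l_inf) / p.k, 80.0)
    cells = set()
    for y in range(int(math.floor(min(t) - a_max)) - 1, int(math.floor(max(t))) + 1):
        birth = y + p.t_anchor
        for d in range(nd):
            age = t[d] - birth
            if age <= 0:
                continue
            L = p.l_inf * (1 - math.exp(-p.k * age))
            if L < lo or L >= hi or L > max_len:
                continue
            cells.add((d, int((L - lo) // r.bin_width)))
    esp = 0.0
    hit_peaks = set()
    for d, b in sorted(cells):
        if (d, b) in peak_of:
            hit_peaks.add(peak_of[(d, b)])
        else:
            esp += values[d, b]
    esp += sum(peak_sum[i] for i in hit_peaks)
    return esp, asp, 10 ** (esp / asp) / 10


class TestScoring:
    def test_rn_bounds_and_esp_asp_order(self, rng):
        counts = rng.poisson(3.0, size=(3, 10))
        counts[0, 4] += 6  # guarantee a peak
        r = restructure(_matrix(counts), ma_window=5)
        for _ in range(60):
            p = ELEFANParams(
                l_inf=rng.uniform(60, 250), k=rng.uniform(0.05, 1.0),
                t_anchor=rng.uniform(0, 1),
            )
            esp, asp, rn = score_growth_curve(r, p)
            assert esp <= asp + 1e-12
            assert 0.0 < rn <= 1.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for rep in range(10):
            counts = rng.poisson(2.5, size=(3, 10))
            counts[rng.integers(3), rng.integers(10)] += 5
            r = restructure(_matrix(counts), ma_window=5)
            try:
                for _ in range(10):
                    p = ELEFANParams(
                        l_inf=rng.uniform(60, 300), k=rng.uniform(0.05, 1.0),
                        t_anchor=rng.uniform(0, 1),
                    )
                    mine = score_growth_curve(r, p)
                    oracle = brute_force_score(r, p)
                    assert mine[0] == pytest.approx(oracle[0], abs=1e-9)
                    assert mine[1] == pytest.approx(oracle[1], abs=1e-9)
                    assert mine[2] == pytest.approx(oracle[2], abs=1e-9)
            except ValueError:
                continue  # ASP = 0 for this matrix

    def test_curve_through_zero_bins_scores_floor(self):
        """A family crossing only zero-score bins has ESP 0, Rn 0.1."""
        counts = np.zeros((1, 12), dtype=int)
        counts[0, 2:5] = [2, 9, 2]
        r = restructure(_matrix(counts), ma_window=5)
        # one crossing, placed in the empty top region where scores are 0
        p = ELEFANParams(l_inf=1000.0, k=0.9, t_anchor=0.895)
        esp, asp, rn = score_growth_curve(r, p)
        assert esp == pytest.approx(0.0, abs=1e-12)
        assert rn == pytest.approx(0.1)

    def test_no_peaks_rejected(self):
        r = restructure(_matrix(np.full(10, 4)), ma_window=5)
        with pytest.raises(ValueError):
            score_growth_curve(r, ELEFANParams(100.0, 0.3, 0.1))


class TestGA:
    def _clean_survey(self, seed=3):
        """Fast-growing, tightly grouped cohorts: a strong test signal."""
        p = GrowthParams(436.5, 0.30)
        return simulate_length_frequency(
            p, cohort_sd=12.0, survival=0.7, max_age=15, selectivity=False,
            catchability=0.2, seed=seed,
        )

    def test_recovers_on_clean_cohort_data(self):
        lfq = bin_lengths(self._clean_survey(), 10.0)
        fit = ga_optimize(lfq, GASettings(seed=4))
        assert fit.estimates["l_inf"] == pytest.approx(436.5, rel=0.08)
        assert fit.estimates["k"] == pytest.approx(0.30, rel=0.12)

    def test_seeded_bit_reproducibility(self):
        lfq = bin_lengths(self._clean_survey(), 10.0)
        a = ga_optimize(lfq, GASettings(population=20, generations=15, seed=7))
        b = ga_optimize(lfq, GASettings(population=20, generations=15, seed=7))
        assert a.estimates == b.estimates
        assert a.fit_stats["rn"] == b.fit_stats["rn"]

    def test_elitism_makes_fitness_monotone(self):
        lfq = bin_lengths(self._clean_survey(), 10.0)
        fit = ga_optimize(lfq, GASettings(population=20, generations=25, seed=8))
        hist = fit.fit_stats["fitness_history"]
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_removing_large_fish_lowers_asymptote(self):
        """Losing all fish above 350 mm drags the estimated l_inf down,
        mirroring the real-survey scarcity of large individuals."""
        full, trunc = [], []
        for seed in (3, 4, 5):
            samples = self._clean_survey(seed)
            cut = [
                LFQSample(date=s.date, lengths=s.lengths[s.lengths <= 350])
                for s in samples
                if (s.lengths <= 350).any()
            ]
            f_full = ga_optimize(bin_lengths(samples, 10.0), GASettings(seed=seed))
            f_cut = ga_optimize(bin_lengths(cut, 10.0), GASettings(seed=seed))
            full.append(f_full.estimates["l_inf"])
            trunc.append(f_cut.estimates["l_inf"])
        assert np.median(trunc) < np.median(full)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            GASettings(bounds={"l_inf": (500.0, 500.0)})


class TestBootstrap:
    def test_two_replicates_recorded(self):
        lfq = bin_lengths(simulate_length_frequency(ELEFAN_TRUTH, seed=5), 10.0)
        fit = bootstrap_elefan(
            lfq, B=2, settings=GASettings(population=12, generations=8), seed=1
        )
        assert len(fit.fit_stats["bootstrap_replicates"]["l_inf"]) == 2
        assert fit.fit_stats["bootstrap_B"] == 2

    def test_intervals_bracket_point_estimate(self):
        lfq = bin_lengths(simulate_length_frequency(ELEFAN_TRUTH, seed=6), 10.0)
        fit = bootstrap_elefan(
            lfq, B=6, settings=GASettings(population=15, generations=10), seed=2
        )
        for nm, (lo, hi) in fit.intervals.items():
            assert lo <= fit.estimates[nm] <= hi

    def test_b_below_two_rejected(self):
        lfq = bin_lengths(simulate_length_frequency(ELEFAN_TRUTH, seed=7), 10.0)
        with pytest.raises(ValueError):
            bootstrap_elefan(lfq, B=1)
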