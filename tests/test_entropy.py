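"""Log-binned ISI-pair entropy estimator and fiber classification."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axondbs import (EntropyParams, amplitude_to_regularize, classify_fiber,
                     entropy_map, fraction_regular, isi_pairs, log_bin_index,
                     pair_entropy, population_isi_pair_histogram,
                     spike_train_entropy)
from axondbs.bursts import fixture_trains


def brute_force_entropy(times, bin0=0.4, kappa=20):
    """Independent oracle: explicit enumeration of the pair distribution."""
    isis = [times[i + 1] - times[i] for i in range(len(times) - 1)]
    cells = Counter()
    for a, b in zip(isis[:-1], isis[1:]):
        ka = math.floor(kappa * math.log10(max(a, bin0) / bin0))
        kb = math.floor(kappa * math.log10(max(b, bin0) / bin0))
        cells[(ka, kb)] += 1
    n = sum(cells.values())
    if n == 0:
        return None
    return -sum((c / n) * math.log2(c / n) for c in cells.values())


class TestIsiPairs:
    def test_two_spikes_give_no_pairs(self):
        assert isi_pairs(np.array([0.0, 10.0])).shape == (0, 2)

    def test_direct_arithmetic(self):
        pairs = isi_pairs(np.array([0.0, 10.0, 20.0, 35.0]))
        assert np.allclose(pairs, [[10.0, 10.0], [10.0, 15.0]])

    def test_periodic_train_pairs_identical(self):
        pairs = isi_pairs(np.arange(0.0, 100.0, 5.0))
        assert np.allclose(pairs, pairs[0])


class TestLogBinIndex:
    @pytest.mark.parametrize("isi,expected", [(0.4, 0), (4.0, 20),
                                              (40.0, 40)])
    def test_closed_form_bins(self, isi, expected):
        assert log_bin_index(isi) == expected

    def test_bins_half_open(self):
        p = EntropyParams()
        edge = 0.4 * 10 ** (1 / 20)
        assert log_bin_index(edge * 0.9999, p) == 0
        assert log_bin_index(edge * 1.0001, p) == 1

    def test_subbin0_isi_warns_and_clamps(self):
        with pytest.warns(UserWarning):
            assert log_bin_index(0.1) == 0

    def test_nonpositive_isi_rejected(self):
        with pytest.raises(ValueError):
            log_bin_index(0.0)


class TestPairEntropy:
    def test_periodic_train_has_zero_entropy(self):
        t = fixture_trains("periodic", {"rate_hz": 100.0,
                                        "epoch_ms": 1000.0})
        assert spike_train_entropy(t) == 0.0

    def test_two_equiprobable_cells_give_one_bit(self):
        t = fixture_trains("alternating", {"isi_short_ms": 5.0,
                                           "isi_long_ms": 50.0,
                                           "n_spikes": 102})
        assert spike_train_entropy(t) == pytest.approx(1.0)

    def test_uniform_over_k_cells_gives_log2_k(self):
        # ISI sequence a,a,b,b repeating: 4 equiprobable pair cells
        isis = np.tile([2.0, 2.0, 20.0, 20.0], 25)
        t = np.concatenate([[0.0], np.cumsum(isis)])[:98]  # 96 pairs
        assert spike_train_entropy(t) == pytest.approx(2.0)

    def test_no_pairs_is_undefined_not_zero(self):
        assert spike_train_entropy(np.array([1.0, 2.0])) is None

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_matches_brute_force_oracle_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        isis = rng.exponential(12.0, size=60) + 0.5
        t = np.concatenate([[0.0], np.cumsum(isis)])
        assert spike_train_entropy(t) == pytest.approx(
            brute_force_entropy(list(t)), abs=1e-12)

    def test_time_rescaling_by_bin_ratio_preserves_entropy(self):
        """Scaling every ISI by 10^(1/kappa) shifts all bins by one and
        leaves the entropy unchanged (rate independence of log binning)."""
        rng = np.random.default_rng(1)
        isis = rng.exponential(10.0, size=200) + 1.0
        t = np.concatenate([[0.0], np.cumsum(isis)])
        scale = 10 ** (1 / 20)
        assert spike_train_entropy(t * scale) == pytest.approx(
            spike_train_entropy(t), abs=1e-12)

    def test_histogram_normalized(self):
        t = fixture_trains("bursty_two_state", {})
        h, hist = pair_entropy(isi_pairs(t), return_histogram=True)
        assert sum(hist.values()) == pytest.approx(1.0)
        assert h >= 0


class TestClassification:
    def test_zero_entropy_without_block_is_regular(self):
        assert classify_fiber(0.0, None) == "regular"

    def test_intrinsic_entropy_is_irregular(self):
        assert classify_fiber(1.49, None) == "irregular"

    def test_block_dominates(self):
        assert classify_fiber(None, "blocked") == "blocked"
        assert classify_fiber(0.2, "blocked") == "blocked"

    def test_silent_undriven_fiber_is_quiescent(self):
        assert classify_fiber(None, None,
                              has_intrinsic_drive=False) == "quiescent"

    def test_counting_rule_for_fraction_regular(self):
        labels = (["regular"] * 50 + ["blocked"] * 10 + ["irregular"] * 40)
        assert fraction_regular(labels) == 0.5

    def test_all_regular(self):
        assert fraction_regular(["regular"] * 100) == 1.0

    def test_amplitude_to_regularize(self):
        sweep = {0.5: 0.1, 1.0: 0.3, 2.0: 0.6, 4.0: 0.9}
        assert amplitude_to_regularize(sweep, 0.5) == 2.0
        assert amplitude_to_regularize({1.0: 0.2}, 0.5) is None
        with pytest.raises(ValueError):
            amplitude_to_regularize({}, 0.5)


class TestPopulationHistogram:
    def test_pooled_mass_is_one(self):
        trains = [fixture_trains("periodic", {"rate_hz": 200.0,
                                              "epoch_ms": 500.0})
                  for _ in range(5)]
        hist = population_isi_pair_histogram(trains)
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_uniform_periodic_population_is_single_cell(self):
        trains = [fixture_trains("periodic", {"rate_hz": 200.0,
                                              "epoch_ms": 500.0})] * 10
        hist = population_isi_pair_histogram(trains)
        assert len(hist) == 1  # one circle at (5 ms, 5 ms)
        (cell, p), = hist.items()
        assert p == 1.0
        assert cell[0] == cell[1] == log_bin_index(5.0)

    def test_empty_population_empty_histogram(self):
        assert population_isi_pair_histogram([]) == {}

    def test_silent_fibers_contribute_nothing(self):
        periodic = fixture_trains("periodic", {"rate_hz": 200.0,
                                               "epoch_ms": 500.0})
        with_silent = population_isi_pair_histogram(
            [periodic, np.empty(0), np.array([1.0])])
        assert with_silent == population_isi_pair_histogram([periodic])


class TestEntropyMap:
    def test_fibers_ordered_by_distance(self):
        import pandas as pd
        df = pd.DataFrame({
            "fiber": [0, 1, 2] * 2,
            "distance_mm": [2.0, 1.0, 3.0] * 2,
            "entropy": [0.5, 0.0, 1.5, 0.7, 0.1, 1.4],
            "label": ["regular"] * 5 + ["blocked"],
            "condition": [100] * 3 + [200] * 3,
        })
        pivot = entropy_map(df)
        assert list(pivot.index) == [1, 0, 2]
        assert pivot.attrs["blocked"].loc[2, 200]
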