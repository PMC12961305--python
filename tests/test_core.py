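"""Joint-interval binning, per-bin averaging, grand average, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jierp
from jierp.core import Triad
from jierp.preprocess import EpochSet


def make_train(onsets_ms):
    n = len(onsets_ms)
    return jierp.StimulationTrain(
        onsets_ms=np.asarray(onsets_ms, dtype=float),
        finger=np.array(["index"] * n, dtype=object),
        block=np.zeros(n, dtype=int),
    )


def make_epochset(epochs, event_index=None, rejected=None):
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[0]
    return EpochSet(
        epochs=epochs,
        time_ms=np.arange(-200, epochs.shape[2] - 200),
        event_index=np.arange(n) if event_index is None else np.asarray(event_index),
        rejected=np.zeros(n, dtype=bool) if rejected is None else np.asarray(rejected),
        channel_labels=[f"CH{i}" for i in range(epochs.shape[1])],
        meta={"n_events_total": n + 2},
    )


class TestComputeTriads:
    def test_interval_arithmetic(self):
        triads = jierp.compute_triads(make_train([0, 300, 900, 3000]))
        assert [(t.event_index, t.k_s, t.k_minus_1_s) for t in triads] == [
            (2, pytest.approx(0.6), pytest.approx(0.3)),
            (3, pytest.approx(2.1), pytest.approx(0.6)),
        ]

    def test_short_trains_yield_no_triads(self):
        assert jierp.compute_triads(make_train([0, 500])) == []

    def test_triad_count_is_n_minus_2(self):
        train = jierp.generate_train(57, seed=0)
        assert len(jierp.compute_triads(train)) == 55


class TestAssignBin:
    def test_two_to_four_second_pair_lands_in_fourth_cell(self):
        # 1-based report cell (4, 4): the (2, 4] x (2, 4] cell
        assert jierp.assign_bin(Triad(2, 3.0, 2.5)) == (3, 3)

    def test_interval_beyond_largest_edge_excluded(self):
        assert jierp.assign_bin(Triad(2, 9.0, 1.0)) is None
        assert jierp.assign_bin(Triad(2, 1.0, 8.5)) is None

    def test_upper_edge_inclusive_membership(self):
        assert jierp.assign_bin(Triad(2, 0.5, 0.5)) == (0, 0)
        assert jierp.assign_bin(Triad(2, 0.5001, 0.5)) == (0, 1)
        assert jierp.assign_bin(Triad(2, 8.0, 8.0)) == (4, 4)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            jierp.assign_bin(Triad(2, 0.0, 1.0))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_binning_matches_bruteforce_scan(self, seed):
        """Vectorized edge search == linear scan over edges, incl. exclusions."""
        rng = np.random.default_rng(seed)
        edges = [0.5, 1.0, 2.0, 4.0, 8.0]

        def scan(x):
            for i, e in enumerate(edges):
                if x <= e:
                    return i
            return None

        counts = np.zeros((5, 5), dtype=int)
        oracle = np.zeros((5, 5), dtype=int)
        n_excl = n_excl_oracle = 0
        ks = np.exp(rng.uniform(np.log(0.1), np.log(10.0), 400))
        k1s = np.exp(rng.uniform(np.log(0.1), np.log(10.0), 400))
        for k, k1 in zip(ks, k1s):
            cell = jierp.assign_bin(Triad(2, k, k1))
            if cell is None:
                n_excl += 1
            else:
                counts[cell] += 1
            r, c = scan(k1), scan(k)
            if r is None or c is None:
                n_excl_oracle += 1
            else:
                oracle[r, c] += 1
        assert np.array_equal(counts, oracle) and n_excl == n_excl_oracle


class TestBuildJierp:
    def _bin_fixture(self, counts_by_cell, n_time=500, seed=0):
        """Epochs + triads planting a given trial count into chosen cells."""
        rng = np.random.default_rng(seed)
        triads, k_for_cell = [], {}
        centers = jierp.BinGrid().centers_s
        n = 0
        for (r, c), m in counts_by_cell.items():
            for _ in range(m):
                triads.append(Triad(n, float(centers[c]), float(centers[r])))
                n += 1
        epochs = rng.normal(size=(n, 2, n_time))
        return make_epochset(epochs), triads

    def test_min_trials_validity_boundary(self):
        ep, triads = self._bin_fixture({(0, 0): 10, (3, 3): 9})
        j = jierp.build_jierp(ep, triads, min_trials=10)
        assert j.valid[0, 0] and not j.valid[3, 3]
        assert j.trial_count[0, 0] == 10 and j.trial_count[3, 3] == 9
        assert np.all(np.isnan(j.amplitude[3, 3]))

    def test_per_bin_mean_matches_bruteforce(self):
        ep, triads = self._bin_fixture({(1, 2): 12, (4, 0): 11})
        j = jierp.build_jierp(ep, triads, min_trials=10, channel=1)
        members = [t.event_index for t in triads if jierp.assign_bin(t) == (1, 2)]
        assert np.allclose(j.amplitude[1, 2], ep.epochs[members, 1].mean(axis=0))

    def test_rejected_epochs_excluded(self):
        ep, triads = self._bin_fixture({(2, 2): 12})
        ep.rejected[:3] = True
        j = jierp.build_jierp(ep, triads, min_trials=5)
        assert j.trial_count[2, 2] == 9
        assert j.meta["n_no_epoch"] == 3

    def test_no_valid_bins_raises(self):
        ep, triads = self._bin_fixture({(0, 0): 4})
        with pytest.raises(ValueError, match="no valid bins"):
            jierp.build_jierp(ep, triads, min_trials=10)

    def test_event_count_conservation(self, noiseless_recording):
        """Pooled trials + exclusions account for every stimulus."""
        ep = jierp.preprocess_pipeline(noiseless_recording, apply_filter=False)
        ep.rejected[::17] = True  # force some rejected epochs
        triads = jierp.compute_triads(noiseless_recording.events)
        j = jierp.build_jierp(ep, triads, min_trials=1)
        m = j.meta
        assert (
            m["n_pooled"] + m["n_out_of_range"] + m["n_no_epoch"]
            + m["n_pre_triad_events"]
            == noiseless_recording.events.n_events
        )

    def test_noiseless_bins_recover_template(self, template):
        """Preset 'none', no noise, no overlap: every valid bin == template."""
        train = jierp.generate_train(
            80, interval_range_ms=(600.0, 7000.0), distribution="uniform", seed=1
        )
        rec = jierp.synthesize_recording(
            train, template=template, spec="none", noise_sd=0.0
        )
        ep = jierp.reject_amplitude(jierp.epoch_events(rec))
        j = jierp.build_jierp(ep, jierp.compute_triads(train), min_trials=3)
        post = j.time_ms >= 0
        for r, c in zip(*np.nonzero(j.valid)):
            assert np.allclose(
                j.amplitude[r, c, post][:300], template.amplitude_uv, atol=1e-9
            )


class TestGrandAverage:
    def _random_jierp(self, seed, valid=None):
        rng = np.random.default_rng(seed)
        amp = rng.normal(size=(5, 5, 20))
        if valid is None:
            valid = np.ones((5, 5), dtype=bool)
        amp[~valid] = np.nan
        return jierp.JierpTensor(
            amplitude=amp,
            trial_count=np.where(valid, 20, 0),
            valid=valid,
            time_ms=np.arange(1, 21),
            grid=jierp.BinGrid(),
        )

    def test_identical_inputs_average_to_themselves(self):
        j = self._random_jierp(0)
        g = jierp.grand_average([j, j, j])
        assert np.allclose(g.amplitude, j.amplitude, equal_nan=True)

    def test_partial_validity_rule(self):
        valid_b = np.ones((5, 5), dtype=bool)
        valid_b[2, 2] = False
        a, b = self._random_jierp(1), self._random_jierp(2, valid_b)
        g = jierp.grand_average([a, b], min_subject_fraction=0.5)
        assert g.valid[2, 2]
        assert np.allclose(g.amplitude[2, 2], a.amplitude[2, 2])
        # with the default 0.8 fraction the same bin is invalid
        g_strict = jierp.grand_average([a, b])
        assert not g_strict.valid[2, 2]

    def test_matches_bruteforce_nanmean(self):
        js = [self._random_jierp(s) for s in range(4)]
        g = jierp.grand_average(js)
        stack = np.stack([j.amplitude for j in js])
        assert np.allclose(g.amplitude, stack.mean(axis=0))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            jierp.grand_average([])


class TestZscore:
    def test_mean_zero_sd_one_across_valid_bins(self):
        rng = np.random.default_rng(3)
        amp = rng.normal(2.0, 3.0, size=(5, 5, 30))
        j = jierp.JierpTensor(
            amplitude=amp, trial_count=np.full((5, 5), 15),
            valid=np.ones((5, 5), bool), time_ms=np.arange(1, 31),
            grid=jierp.BinGrid(),
        )
        zj = jierp.zscore_latencywise(j)
        zv = zj.z[zj.valid]
        assert np.allclose(zv.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(zv.std(axis=0, ddof=1), 1.0, atol=1e-12)
        # brute-force oracle at one latency
        x = amp.reshape(25, 30)[:, 7]
        assert np.allclose(zv[:, 7], (x - x.mean()) / x.std(ddof=1))

    def test_constant_latency_flagged_degenerate(self):
        amp = np.random.default_rng(0).normal(size=(5, 5, 3))
        amp[:, :, 1] = 4.0
        j = jierp.JierpTensor(
            amplitude=amp, trial_count=np.full((5, 5), 15),
            valid=np.ones((5, 5), bool), time_ms=np.arange(1, 4),
            grid=jierp.BinGrid(),
        )
        zj = jierp.zscore_latencywise(j)
        assert zj.degenerate_latencies.tolist() == [False, True, False]
        assert np.all(zj.z[zj.valid][:, 1] == 0.0)

    def test_too_few_valid_bins_rejected(self):
        valid = np.zeros((5, 5), bool)
        valid[0, 0] = True
        amp = np.full((5, 5, 3), np.nan)
        amp[0, 0] = 1.0
        j = jierp.JierpTensor(
            amplitude=amp, trial_count=valid * 15, valid=valid,
            time_ms=np.arange(1, 4), grid=jierp.BinGrid(),
        )
        with pytest.raises(ValueError):
            jierp.zscore_latencywise(j)


class TestSuppressionSignature:
    def test_short_previous_interval_column_suppressed_at_p50(self, template):
        """Planted early/late suppression, noise -> 0: at 50 ms the z-scored
        JIERP is negative throughout the k <= 0.5 s column, and that column's
        mean is the minimum over columns."""
        train = jierp.generate_train(900, seed=21)
        rec = jierp.synthesize_recording(
            train, template=template, spec="early_late_suppression", noise_sd=0.0
        )
        ep = jierp.preprocess_pipeline(rec, apply_filter=False)
        j = jierp.build_jierp(ep, jierp.compute_triads(train), min_trials=10)
        zj = jierp.zscore_latencywise(j)
        t50 = np.nonzero(zj.time_ms == 50)[0][0]
        zmap = zj.z[:, :, t50]
        assert np.all(zmap[:, 0][j.valid[:, 0]] < 0)
        col_means = np.nanmean(np.where(j.valid, zmap, np.nan), axis=0)
        assert np.argmin(col_means) == 0
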