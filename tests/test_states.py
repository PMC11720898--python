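"""Connectivity-state clustering, assignment, and temporal metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfnckit.states import (
    ConnectivityStates,
    assign_windows,
    choose_k,
    fit_states,
    run_lengths,
    state_metrics,
    subject_state_maps,
)
from dfnckit.fnc import make_windows
from dfnckit import synth


def metrics_oracle(seq):
    """Brute-force run enumeration for the temporal metrics identities."""
    runs = []
    cur, length = seq[0], 1
    for x in seq[1:]:
        if x == cur:
            length += 1
        else:
            runs.append((cur, length))
            cur, length = x, 1
    runs.append((cur, length))
    return runs


class TestChooseK:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0, 0.1, size=(60, 8)),
            rng.normal(5, 0.1, size=(60, 8)),
        ])
        k, curves = choose_k(X, seed=0, B=20)
        assert k == 2
        assert curves["k_silhouette"] == 2

    def test_three_separated_clouds(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [8, 0], [4, 7]], dtype=float)
        X = np.vstack([rng.normal(c, 0.2, size=(50, 2)) for c in centers])
        k, curves = choose_k(X, seed=1, B=20)
        assert k == 3
        assert curves["k_silhouette"] == 3

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            choose_k(np.ones((50, 4)))

    def test_silhouette_of_duplicated_points_is_one(self):
        from sklearn.metrics import silhouette_score

        X = np.repeat([[0.0, 0.0], [9.0, 9.0]], 10, axis=0)
        labels = np.repeat([0, 1], 10)
        assert silhouette_score(X, labels) == pytest.approx(1.0)


class TestFitStates:
    def test_two_state_centroid_recovery(self, two_state_windows):
        """Centroid mean edge strength recovers the 0.1 / 0.45 generator values."""
        Z, _ = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        means = np.tanh(model.cluster_centers_.mean(axis=1))
        assert means[0] == pytest.approx(0.1, abs=0.05)
        assert means[1] == pytest.approx(0.45, abs=0.05)
        assert means[0] < means[1]  # state 1 weakly connected by convention

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            fit_states(np.random.default_rng(2).normal(size=(20, 5)), k=1)

    def test_row_permutation_leaves_centroids(self, two_state_windows):
        Z, _ = two_state_windows
        perm = np.random.default_rng(3).permutation(len(Z))
        a = fit_states(Z, k=2, seed=0).cluster_centers_
        b = fit_states(Z[perm], k=2, seed=0).cluster_centers_
        assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=1e-6)


class TestAssignWindows:
    def test_window_equal_to_centroid(self, two_state_windows):
        Z, _ = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        labels = model.predict(model.cluster_centers_)
        assert list(labels) == [0, 1]

    def test_affine_invariance(self, two_state_windows):
        """Pearson assignment ignores positive scaling and offsets."""
        Z, _ = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        base = model.predict(Z)
        assert np.array_equal(model.predict(0.5 * Z + 3.0), base)

    def test_planted_state_accuracy(self, two_state_windows):
        Z, truth = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        acc = (assign_windows(Z, model) == truth).mean()
        assert acc > 0.95

    def test_zero_variance_window_falls_back(self, two_state_windows):
        Z, _ = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        flat = np.full((1, Z.shape[1]), 0.7)
        labels = model.predict(flat)
        assert labels.shape == (1,)
        assert model.fallback_windows_.tolist() == [0]

    def test_edge_length_mismatch_rejected(self, two_state_windows):
        Z, _ = two_state_windows
        model = fit_states(Z, k=2, seed=0)
        with pytest.raises(ValueError):
            model.predict(Z[:, :10])


class TestStateMetrics:
    def test_worked_example(self):
        m = state_metrics([1, 1, 2, 2, 2, 1], n_states=2)
        assert np.allclose(m.fractional_windows, [0.5, 0.5])
        assert np.allclose(m.mean_dwell, [1.5, 3.0])
        assert m.n_transitions == 2
        assert m.transition_matrix[0, 1] == pytest.approx(0.5)

    def test_constant_sequence(self):
        m = state_metrics(np.zeros(20, dtype=int), n_states=2)
        assert np.allclose(m.fractional_windows, [1.0, 0.0])
        assert m.n_transitions == 0
        assert m.mean_dwell[0] == 20
        assert 1 in m.unvisited

    def test_alternating_sequence(self):
        seq = np.tile([0, 1], 39)  # W = 78
        m = state_metrics(seq, n_states=2)
        assert m.n_transitions == 77
        assert np.allclose(m.mean_dwell, [1.0, 1.0])

    def test_dwell_seconds_conversion(self):
        m = state_metrics([0, 0, 1, 1], n_states=2, step_seconds=20 * 0.392)
        assert m.dwell_seconds[0] == pytest.approx(2 * 7.84)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=120))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_against_run_oracle(self, seq):
        """Sum of fractions = 1; transitions = runs - 1; dwell*visits sums to W."""
        seq = np.asarray(seq)
        m = state_metrics(seq, n_states=3)
        runs = metrics_oracle(list(seq))
        assert m.fractional_windows.sum() == pytest.approx(1.0)
        assert m.n_transitions == len(runs) - 1
        visits = np.bincount([s for s, _ in runs], minlength=3)
        assert (m.mean_dwell * visits).sum() == pytest.approx(len(seq))
        rowsums = np.nansum(m.transition_matrix, axis=1)
        defined = np.unique(seq[:-1]) if len(seq) > 1 else []
        for s in defined:
            assert rowsums[s] == pytest.approx(1.0)


class TestSubjectStateMaps:
    def _windows(self, seed=4):
        p = synth.StateGenParams(K=4, T=400, stay_prob=(0.95, 0.95), seed=seed)
        ts = synth.gen_timeseries(p, synth.gen_state_path(p))
        return make_windows(ts, window=50, step=25)

    def test_all_one_state(self):
        wf = self._windows()
        seq = np.zeros(wf.W, dtype=int)
        maps = subject_state_maps(wf, seq, n_states=2)
        assert set(maps) == {0}
        assert np.allclose(maps[0].values, wf.matrices.mean(axis=0))

    def test_one_window_per_state(self):
        wf = self._windows()
        seq = np.zeros(wf.W, dtype=int)
        seq[3] = 1
        maps = subject_state_maps(wf, seq, n_states=2)
        assert np.allclose(maps[1].values, wf.matrices[3])

    def test_strong_state_map_has_larger_mean_edge(self, two_state_windows):
        Z, truth = two_state_windows
        from dfnckit.fnc import from_edges, WindowedFNC

        mats = from_edges(np.tanh(Z), diag=1.0)
        wf = WindowedFNC(mats, 50, 20, np.arange(len(Z)) * 20)
        maps = subject_state_maps(wf, truth, n_states=2)
        from dfnckit.fnc import to_edges

        assert to_edges(maps[1].values).mean() > to_edges(maps[0].values).mean()
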