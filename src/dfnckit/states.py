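"""Connectivity-state estimation and temporal state metrics.

Recurring whole-brain connectivity patterns ("brain states") are
estimated by k-means over windowed-FNC edge vectors pooled from a
reference group.  The number of states is validated with the gap
statistic (Tibshirani et al.: uniform reference sets over the data's
bounding box) and the mean silhouette.  Centroids are ordered by
ascending mean edge strength, so state 1 is the weakly-connected and
state 2 the strongly-connected pattern.  Each subject's windows are then
assigned to the nearest centroid by Pearson correlation, producing a
state sequence from which fractional windows, mean dwell time, number of
transitions and the empirical transition matrix are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fnc import WindowedFNC, FNCMatrix, from_edges

__all__ = [
    "ConnectivityStates",
    "StateMetrics",
    "choose_k",
    "gap_statistic",
    "fit_states",
    "assign_windows",
    "state_metrics",
    "subject_state_maps",
    "run_lengths",
]


def _as_edge_matrix(windows: WindowedFNC | np.ndarray) -> np.ndarray:
    if isinstance(windows, WindowedFNC):
        return windows.z_edges()
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2:
        raise ValueError("windows must be (W, E) edge vectors or a WindowedFNC")
    return X


def _log_wk(X: np.ndarray, labels: np.ndarray) -> float:
    """log of the within-cluster dispersion W_k = sum_r D_r / (2 n_r)."""
    wk = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if len(pts) > 1:
            wk += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(np.log(max(wk, np.finfo(float).tiny)))


def gap_statistic(
    X: np.ndarray,
    k_values: list[int],
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
    reference: str = "pca",
) -> tuple[np.ndarray, np.ndarray]:
    """Gap statistic over candidate cluster counts.

    gap(k) = E*[log W_k] - log W_k, the expectation estimated from B
    uniform reference draws over the data's bounding box.  With
    ``reference='pca'`` (default) the box is aligned with the data's
    principal axes — the variant recommended for elongated, correlated
    feature clouds such as Fisher-z edge vectors, where the axis-aligned
    box (``reference='box'``) grossly over-disperses the reference and
    lets the gap creep upward with k.  Also returns
    s_k = sd * sqrt(1 + 1/B), the simulation-error term used in the
    "smallest k with gap(k) >= gap(k+1) - s_{k+1}" selection rule.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    if reference == "pca":
        _, _, Vt = np.linalg.svd(X - mu, full_matrices=False)
        Xr = (X - mu) @ Vt.T
    elif reference == "box":
        Vt = np.eye(X.shape[1])
        Xr = X - mu
    else:
        raise ValueError("reference must be 'pca' or 'box'")
    lo, hi = Xr.min(axis=0), Xr.max(axis=0)
    gaps, sks = np.empty(len(k_values)), np.empty(len(k_values))
    ref_logs = np.empty(B)
    for i, k in enumerate(k_values):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        obs = _log_wk(X, km.fit_predict(X))
        for b in range(B):
            ref = rng.uniform(lo, hi, size=X.shape) @ Vt + mu
            ref_logs[b] = _log_wk(ref, KMeans(
                n_clusters=k, n_init=n_init, random_state=seed).fit_predict(ref))
        gaps[i] = ref_logs.mean() - obs
        sks[i] = ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return gaps, sks


def choose_k(
    windows: WindowedFNC | np.ndarray,
    k_range: range | list[int] = range(2, 5),
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, dict]:
    """Select the number of connectivity states by gap + silhouette.

    Runs the gap statistic (with one extra k beyond the range so the
    Tibshirani decision rule is evaluable at the top of the range) and the
    mean silhouette for every k in ``k_range``; the selected k is the gap
    choice, and the silhouette-maximising k is reported alongside.

    Returns ``(k, curves)`` with curves = {'k_values', 'gap', 'gap_sk',
    'silhouette', 'k_gap', 'k_silhouette'}.
    """
    X = _as_edge_matrix(windows)
    ks = sorted(k_range)
    if X.shape[0] < max(ks) + 1:
        raise ValueError("not enough windows for the requested cluster counts")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate windows: all points identical")
    ks_ext = ks + [ks[-1] + 1]
    gaps, sks = gap_statistic(X, ks_ext, B=B, seed=seed, n_init=n_init)
    k_gap = ks[-1]
    for i, k in enumerate(ks):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            k_gap = k
            break
    sil = np.array([
        silhouette_score(X, KMeans(n_clusters=k, n_init=n_init,
                                   random_state=seed).fit_predict(X))
        for k in ks
    ])
    k_sil = ks[int(np.argmax(sil))]
    curves = {
        "k_values": np.array(ks),
        "gap": gaps[: len(ks)],
        "gap_sk": sks[: len(ks)],
        "silhouette": sil,
        "k_gap": k_gap,
        "k_silhouette": k_sil,
    }
    return k_gap, curves


class ConnectivityStates(ClusterMixin, BaseEstimator):
    """K-means connectivity-state model with correlation-based assignment.

    Fit on pooled reference-group windows (W x E Fisher-z edge vectors);
    centroids are then reordered by ascending mean edge strength so that
    ``state 1`` (label 0) is the weakly-connected and the last state the
    most strongly connected pattern.  ``predict`` assigns new windows to
    the centroid with the highest Pearson correlation (scale- and
    offset-invariant), falling back to Euclidean distance for
    zero-variance window vectors.

    Parameters
    ----------
    n_states : int
        Number of states k, >= 2.
    n_init : int
        k-means restarts (k-means++ seeding), default 100.
    random_state : int
        Seed recorded in the fitted model.

    Attributes
    ----------
    cluster_centers_ : (k, E) ndarray, ordered by mean edge strength.
    labels_ : training-window state labels (0-based).
    inertia_ : k-means objective at the selected restart.
    """

    def __init__(self, n_states: int = 2, n_init: int = 100, random_state: int = 0):
        self.n_states = n_states
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: WindowedFNC | np.ndarray, y=None) -> "ConnectivityStates":
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        X = _as_edge_matrix(X)
        km = KMeans(
            n_clusters=self.n_states,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(X)
        order = np.argsort(km.cluster_centers_.mean(axis=1))
        relabel = np.empty_like(order)
        relabel[order] = np.arange(self.n_states)
        self.cluster_centers_ = km.cluster_centers_[order]
        self.labels_ = relabel[km.labels_]
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: WindowedFNC | np.ndarray) -> np.ndarray:
        """Assign windows to states by maximal Pearson correlation.

        Ties go to the lower-numbered state; zero-variance windows fall
        back to Euclidean distance (indices recorded in
        ``self.fallback_windows_``).
        """
        X = _as_edge_matrix(X)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError("edge-vector length mismatch with fitted centroids")
        C = self.cluster_centers_
        Cc = C - C.mean(axis=1, keepdims=True)
        Cn = np.linalg.norm(Cc, axis=1)
        Xc = X - X.mean(axis=1, keepdims=True)
        Xn = np.linalg.norm(Xc, axis=1)
        degenerate = Xn == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Xc @ Cc.T) / np.outer(Xn, Cn)
        labels = np.argmax(np.round(R, 12), axis=1)  # argmax is first-max -> low state
        if degenerate.any():
            d = ((X[degenerate, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            labels[degenerate] = np.argmin(d, axis=1)
        self.fallback_windows_ = np.flatnonzero(degenerate)
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class StateMetrics:
    """Temporal metrics of a per-window state sequence.

    ``fractional_windows[s]`` — proportion of windows in state s;
    ``mean_dwell[s]`` — mean run length in windows (0 if never visited);
    ``n_transitions`` — number of label changes;
    ``transition_matrix[i, j]`` — empirical P(next = j | current = i),
    rows of never-left states are NaN.
    ``dwell_seconds`` available when the window step duration is known.
    """

    fractional_windows: np.ndarray
    mean_dwell: np.ndarray
    n_transitions: int
    transition_matrix: np.ndarray
    n_windows: int
    step_seconds: float | None = None
    unvisited: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def dwell_seconds(self) -> np.ndarray | None:
        if self.step_seconds is None:
            return None
        return self.mean_dwell * self.step_seconds


def run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence: (labels, lengths) per run."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return np.array([], dtype=seq.dtype), np.array([], dtype=int)
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [seq.size]])
    return seq[starts], ends - starts


def state_metrics(
    seq: np.ndarray, n_states: int | None = None, step_seconds: float | None = None
) -> StateMetrics:
    """Fractional windows, mean dwell, transition count and matrix.

    ``step_seconds`` (= step * TR) converts dwell from windows to seconds.
    States indexed 0-based; a sequence in 1..k is accepted and shifted.
    """
    seq = np.asarray(seq, dtype=int)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    if seq.min() == 1 and (n_states is None or seq.max() == n_states):
        seq = seq - 1  # tolerate 1-based sequences
    k = int(n_states if n_states is not None else seq.max() + 1)
    W = seq.size
    frac = np.bincount(seq, minlength=k) / W
    labels, lengths = run_lengths(seq)
    dwell = np.zeros(k)
    for s in range(k):
        sel = labels == s
        if sel.any():
            dwell[s] = lengths[sel].mean()
    trans = int((seq[1:] != seq[:-1]).sum())
    counts = np.zeros((k, k))
    np.add.at(counts, (seq[:-1], seq[1:]), 1)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / rowsum
    return StateMetrics(
        fractional_windows=frac,
        mean_dwell=dwell,
        n_transitions=trans,
        transition_matrix=P,
        n_windows=W,
        step_seconds=step_seconds,
        unvisited=np.flatnonzero(frac == 0),
    )


def fit_states(
    windows: WindowedFNC | np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 100,
) -> ConnectivityStates:
    """Fit the k-state connectivity model on pooled reference windows."""
    return ConnectivityStates(n_states=k, n_init=n_init, random_state=seed).fit(windows)


def assign_windows(
    windows: WindowedFNC | np.ndarray, model: ConnectivityStates
) -> np.ndarray:
    """Per-window state labels (0-based) for one subject."""
    return model.predict(windows)


def subject_state_maps(
    wfnc: WindowedFNC, seq: np.ndarray, n_states: int = 2
) -> dict[int, FNCMatrix]:
    """Per-state element-wise mean connectivity matrix of assigned windows.

    States with no assigned windows are absent from the returned dict.
    """
    seq = np.asarray(seq, dtype=int)
    if seq.size != wfnc.W:
        raise ValueError("state sequence length must match window count")
    out: dict[int, FNCMatrix] = {}
    for s in range(n_states):
        sel = seq == s
        if sel.any():
            out[s] = FNCMatrix(wfnc.matrices[sel].mean(axis=0), scale=wfnc.scale)
    return out
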