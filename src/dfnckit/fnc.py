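"""Static and sliding-window functional network connectivity (FNC).

FNC is the Pearson correlation between the time courses of paired
networks.  Static FNC uses the whole scan; dynamic FNC slides a
rectangular window (default 50 TR = 19.6 s at TR 0.392 s) along the scan
and computes one K x K correlation matrix per window.  The per-edge
variance of FNC across windows is the simplest summary of connectivity
dynamics.  Edge values are Fisher r-to-z transformed by default before
variance computation, averaging and group statistics; raw-r mode is
available everywhere via ``fisher_z=False``.

Note on the window step: at T = 1600 volumes and w = 50 TR the default
step of 20 TR yields the 78 windows this pipeline is calibrated to; a
2-TR step (0.784 s) is also supported via the ``step`` parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FNCMatrix",
    "WindowedFNC",
    "static_fnc",
    "SlidingWindowFNC",
    "make_windows",
    "dfnc_variance",
    "aggregate",
    "to_edges",
    "from_edges",
    "fisher_z",
    "inverse_fisher_z",
]

DEFAULT_WINDOW = 50
DEFAULT_STEP = 20
#: clip |r| below 1 before arctanh so z stays finite
_R_CLIP = 1.0 - 1e-12


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z variance-stabilising transform, arctanh(r)."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def to_edges(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector (length K(K-1)/2) of a square matrix."""
    mat = np.asarray(mat)
    k = mat.shape[-1]
    iu = np.triu_indices(k, 1)
    return mat[..., iu[0], iu[1]]


def from_edges(edges: np.ndarray, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric K x K matrix from an upper-triangle vector."""
    edges = np.asarray(edges, dtype=float)
    e = edges.shape[-1]
    k = int((1 + np.sqrt(1 + 8 * e)) / 2)
    if k * (k - 1) // 2 != e:
        raise ValueError(f"edge vector length {e} is not K(K-1)/2 for integer K")
    mat = np.zeros(edges.shape[:-1] + (k, k))
    iu = np.triu_indices(k, 1)
    mat[..., iu[0], iu[1]] = edges
    mat[..., iu[1], iu[0]] = edges
    mat[..., np.arange(k), np.arange(k)] = diag
    return mat


@dataclass
class FNCMatrix:
    """K x K connectivity matrix; ``scale`` records 'r' or 'z'."""

    values: np.ndarray
    scale: str = "r"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FNC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FNC matrix must be symmetric")
        if self.scale == "r" and (np.abs(to_edges(v)) > 1 + 1e-12).any():
            raise ValueError("r-scale entries must lie in [-1, 1]")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def edges(self) -> np.ndarray:
        return to_edges(self.values)


@dataclass
class WindowedFNC:
    """Stack of W per-window K x K connectivity matrices.

    ``starts`` holds the 0-based first-volume index of each window;
    W = floor((T - w) / s) + 1 for window length w and step s.
    """

    matrices: np.ndarray  # (W, K, K)
    window: int
    step: int
    starts: np.ndarray
    scale: str = "r"

    @property
    def W(self) -> int:
        return self.matrices.shape[0]

    @property
    def K(self) -> int:
        return self.matrices.shape[1]

    def edges(self) -> np.ndarray:
        """(W, K(K-1)/2) edge-vector view of the window stack."""
        return to_edges(self.matrices)

    def z_edges(self) -> np.ndarray:
        e = self.edges()
        return e if self.scale == "z" else fisher_z(e)


def _corrcoef_checked(ts: np.ndarray, labels=None) -> np.ndarray:
    sd = ts.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = [labels[i] for i in bad] if labels else list(bad)
        raise ValueError(f"constant time series for network(s) {names}")
    return np.corrcoef(ts, rowvar=False)


def static_fnc(ts: np.ndarray, labels: list[str] | None = None) -> FNCMatrix:
    """Whole-scan Pearson correlation matrix of a T x K series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be T x K")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    return FNCMatrix(_corrcoef_checked(ts, labels), scale="r", labels=labels)


class SlidingWindowFNC(TransformerMixin, BaseEstimator):
    """Sliding-window connectivity transformer.

    ``transform`` maps a T x K time-series array to the (W, E) stack of
    per-window edge vectors (E = K(K-1)/2), Fisher-z by default; use
    :meth:`windowed` for the full matrix stack with window bookkeeping.

    Parameters
    ----------
    window : int
        Window length in TR (default 50).
    step : int
        Step between window starts in TR (default 20).
    fisher_z : bool
        Return z-transformed edges from ``transform`` (default True).
    """

    def __init__(self, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                 fisher_z: bool = True):
        self.window = window
        self.step = step
        self.fisher_z = fisher_z

    def fit(self, X=None, y=None) -> "SlidingWindowFNC":
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        return self

    def windowed(self, ts: np.ndarray, labels=None) -> WindowedFNC:
        self.fit()
        ts = np.asarray(ts, dtype=float)
        T = ts.shape[0]
        if self.window > T:
            raise ValueError(f"window {self.window} exceeds series length {T}")
        starts = np.arange(0, T - self.window + 1, self.step)
        mats = np.stack(
            [_corrcoef_checked(ts[s : s + self.window], labels) for s in starts]
        )
        self.n_windows_ = len(starts)
        return WindowedFNC(mats, self.window, self.step, starts)

    def transform(self, ts: np.ndarray) -> np.ndarray:
        w = self.windowed(ts)
        return w.z_edges() if self.fisher_z else w.edges()


def make_windows(ts: np.ndarray, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP, labels=None) -> WindowedFNC:
    """Per-window Pearson connectivity of a T x K series (r scale)."""
    return SlidingWindowFNC(window=window, step=step).windowed(ts, labels)


def dfnc_variance(wfnc: WindowedFNC, fisher: bool = True) -> FNCMatrix:
    """Per-edge sample variance of connectivity across windows.

    Computed on the Fisher-z scale by default (``fisher=False`` for raw r);
    the diagonal is 0 since r-scale diagonals are constant.
    """
    if wfnc.W < 2:
        raise ValueError("variance needs at least 2 windows")
    edges = wfnc.z_edges() if fisher else wfnc.edges()
    var = edges.var(axis=0, ddof=1)
    return FNCMatrix(from_edges(var, diag=0.0), scale="var", labels=None)


def aggregate(mat: FNCMatrix | np.ndarray, level: str = "whole") -> np.ndarray | float:
    """Aggregate a symmetric K x K matrix at a reporting level.

    ``edge``    -> upper-triangle vector, length K(K-1)/2
    ``network`` -> per-network mean of its K-1 off-diagonal connections
    ``whole``   -> mean over the upper triangle
    """
    v = mat.values if isinstance(mat, FNCMatrix) else np.asarray(mat, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("aggregate needs a square matrix")
    k = v.shape[0]
    if level == "edge":
        return to_edges(v)
    if level == "network":
        off = v.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1) / (k - 1)
    if level == "whole":
        return float(to_edges(v).mean())
    raise ValueError(f"unknown level {level!r}")
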