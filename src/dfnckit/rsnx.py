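"""Resting-state network time-series extraction.

Nuisance regression (motion + tissue signals), temporal band-pass
filtering of the BOLD band (0.01-0.1 Hz), group-level spatial ICA, and
two-stage dual regression mapping group network maps to subject-specific
time courses and maps.

Dual regression follows the standard two-stage least-squares procedure:
stage 1 regresses each volume's voxel vector on the (variance-normalised)
group spatial maps, giving one time course per map; stage 2 regresses each
voxel's time course on those courses, giving one subject map per network.
Both stages are multiple (joint) regressions with an intercept, so
correlated maps are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA, PCA

__all__ = [
    "RSNSet",
    "nuisance_regress",
    "bandpass",
    "group_ica",
    "DualRegression",
    "dual_regression",
    "match_components",
]


@dataclass
class RSNSet:
    """A set of K resting-state network maps on one voxel grid.

    ``maps`` is (K, nx, ny, nz) (or (K, V) flat); ``labels`` unique names;
    ``classes`` optional 'primary' / 'association' tags per map.
    """

    maps: np.ndarray
    labels: list[str] | None = None
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        k = self.maps.shape[0]
        if k < 2:
            raise ValueError("need at least 2 network maps")
        if self.labels is None:
            self.labels = [f"net{i:02d}" for i in range(k)]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("map labels must be unique")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    def flat(self) -> np.ndarray:
        return self.maps.reshape(self.K, -1)


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def nuisance_regress(data: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise ``data`` (T x V) against confound time series (T x C).

    An intercept is always included, so residuals are mean-centred and
    orthogonal to every confound column.  Rank-deficient designs are
    rejected with the offending columns named.
    """
    data = np.asarray(data, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != data.shape[0]:
        raise ValueError("data and confounds must share the time axis")
    X = _design_with_intercept(confounds)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        acc = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([acc, X[:, j]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(j - 1)
            else:
                acc = cand
        raise ValueError(f"confound design is rank deficient (collinear columns {bad})")
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def bandpass(
    data: np.ndarray,
    low: float = 0.01,
    high: float = 0.1,
    fs: float = 1.0 / 0.392,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 0).

    Default band 0.01-0.1 Hz at the 0.392 s TR sampling rate.  Forward-
    backward (filtfilt) application removes phase distortion; the DC
    component is eliminated by the high-pass edge.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz at or above Nyquist {fs / 2:.3f} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=0)


def group_ica(
    data: np.ndarray,
    n_components: int = 30,
    seed: int = 0,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial group ICA on temporally concatenated data (N x V).

    PCA reduction/whitening to ``n_components`` followed by fixed-point
    (FastICA) unmixing; deterministic for a fixed seed.  Returns
    ``(components, mixing)`` with components (n_components, V) spatial maps
    and mixing (N, n_components) the associated time courses/loadings.
    Components are defined up to sign and permutation; use
    :func:`match_components` to align them with references.
    """
    data = np.asarray(data, dtype=float)
    if min(data.shape) < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds data rank bound {min(data.shape)}"
        )
    rank = np.linalg.matrix_rank(data - data.mean(axis=0))
    if rank < n_components:
        raise ValueError(f"data rank {rank} insufficient for {n_components} components")
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
    )
    mixing_sources = ica.fit_transform(data.T)  # V x n_components (spatial sources)
    components = mixing_sources.T
    mixing = ica.mixing_  # N x n_components
    return components, mixing


def match_components(
    components: np.ndarray, references: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy |r|-ranking of components against reference maps.

    Returns (order, r) so that ``components[order[i]]`` is the best
    remaining match for ``references[i]`` with signed correlation ``r[i]``.
    A helper for the manual component-to-network labelling step; it ranks,
    it does not classify.
    """
    comps = np.asarray(components, dtype=float)
    refs = np.asarray(references, dtype=float)
    cz = (comps - comps.mean(1, keepdims=True)) / comps.std(1, keepdims=True)
    rz = (refs - refs.mean(1, keepdims=True)) / refs.std(1, keepdims=True)
    R = rz @ cz.T / comps.shape[1]  # n_refs x n_comps
    order = np.full(refs.shape[0], -1, dtype=int)
    rvals = np.zeros(refs.shape[0])
    free = list(range(comps.shape[0]))
    for i in np.argsort(-np.abs(R).max(axis=1)):
        j = max(free, key=lambda c: abs(R[i, c]))
        order[i], rvals[i] = j, R[i, j]
        free.remove(j)
    return order, rvals


class DualRegression(BaseEstimator):
    """Two-stage dual regression estimator.

    Parameters
    ----------
    normalize_maps : bool
        Variance-normalise the spatial regressors in stage 1 (the common
        FSL-style convention); the fitted time courses then carry the
        amplitude.

    Attributes
    ----------
    maps_ : (K, V) ndarray
        Flattened group maps the estimator was fitted with.
    grid_ : tuple
        The voxel grid of the group maps.
    """

    def __init__(self, normalize_maps: bool = True):
        self.normalize_maps = normalize_maps

    def fit(self, rsns: RSNSet | np.ndarray, y=None) -> "DualRegression":
        maps = rsns.maps if isinstance(rsns, RSNSet) else np.asarray(rsns, dtype=float)
        if maps.ndim < 2:
            raise ValueError("maps must be at least 2-D")
        self.grid_ = maps.shape[1:]
        self.maps_ = maps.reshape(maps.shape[0], -1)
        X = self.maps_.T  # V x K
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("group maps are rank deficient")
        if self.normalize_maps:
            X = X / X.std(axis=0, ddof=0)
        self._X1 = _design_with_intercept(X)
        return self

    def transform(self, volumes: np.ndarray) -> np.ndarray:
        """Stage 1: subject 4D data -> (T, K) network time courses."""
        data = self._flatten(volumes)  # T x V
        beta, *_ = np.linalg.lstsq(self._X1, data.T, rcond=None)
        return beta[1:].T

    def subject_maps(self, volumes: np.ndarray, series: np.ndarray | None = None) -> np.ndarray:
        """Stage 2: regress each voxel's time course on the stage-1 series.

        Returns subject-specific maps with the fitted grid restored.
        """
        data = self._flatten(volumes)
        if series is None:
            series = self.transform(volumes)
        X2 = _design_with_intercept(np.asarray(series, dtype=float))
        beta, *_ = np.linalg.lstsq(X2, data, rcond=None)
        return beta[1:].reshape((series.shape[1],) + self.grid_)

    def fit_transform(self, rsns, volumes):
        return self.fit(rsns).transform(volumes)

    def _flatten(self, volumes: np.ndarray) -> np.ndarray:
        vols = np.asarray(volumes, dtype=float)
        if vols.ndim == 2:  # already T x V
            if vols.shape[1] != self.maps_.shape[1]:
                raise ValueError("voxel count mismatch with fitted maps")
            return vols
        if vols.shape[:-1] != self.grid_:
            raise ValueError(
                f"volume grid {vols.shape[:-1]} does not match map grid {self.grid_}"
            )
        return vols.reshape(-1, vols.shape[-1]).T


def dual_regression(
    volumes: np.ndarray, rsns: RSNSet | np.ndarray, normalize_maps: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: returns (T x K series, subject maps)."""
    dr = DualRegression(normalize_maps=normalize_maps).fit(rsns)
    series = dr.transform(volumes)
    return series, dr.subject_maps(volumes, series)
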