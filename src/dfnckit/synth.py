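"""Synthetic cohorts for dynamic functional connectivity analysis.

The generators in this module emulate the statistical structure the dFNC
pipeline assumes: network BOLD time series that switch between a small
number of hidden covariance "states" (a weakly- and a strongly-connected
regime by default), 4D volumes mixed from spatial maps, rigid-body motion
traces with planted spike outliers, and cohort tables with injected linear
age effects on connectivity.  Every generator exports its ground truth so
downstream recovery can be scored against planted values.

The hidden-state process is a first-order Markov chain at volume
resolution — the minimal process that yields state persistence on the
5-10 s scale observed in neonatal dFNC — started from its stationary
distribution.  State covariances default to constant-correlation blocks
(weak off-diagonal 0.1, strong 0.45) with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateGenParams",
    "GroundTruth",
    "constant_correlation",
    "two_state_covs",
    "gen_state_path",
    "gen_timeseries",
    "gen_4d",
    "gen_motion",
    "gen_cohort",
]

#: default off-diagonal correlations of the two hidden states
WEAK_R = 0.1
STRONG_R = 0.45


def two_state_covs(
    K: int,
    weak_mean: float = WEAK_R,
    strong_mean: float = STRONG_R,
    contrast: float = 0.15,
) -> list[np.ndarray]:
    """Default weak/strong state covariances with distinct edge patterns.

    Each state's mean off-diagonal correlation equals ``weak_mean`` /
    ``strong_mean`` exactly, but the states carry different spatial
    patterns: the weak state concentrates its connectivity within the
    "primary" block (first ceil(K/2) networks), the strong state within
    the "association" block (the rest).  Distinct patterns are essential:
    correlation-based state assignment is offset- and scale-invariant, so
    states differing only in overall level would be indistinguishable by
    construction.
    """
    if K < 4:
        return [constant_correlation(K, weak_mean), constant_correlation(K, strong_mean)]
    p = (K + 1) // 2
    within_primary = np.zeros((K, K), dtype=bool)
    within_primary[:p, :p] = True
    within_assoc = np.zeros((K, K), dtype=bool)
    within_assoc[p:, p:] = True
    np.fill_diagonal(within_primary, False)
    np.fill_diagonal(within_assoc, False)
    E = K * (K - 1) // 2

    def build(mean: float, boost: np.ndarray) -> np.ndarray:
        n_boost = int(boost.sum()) // 2
        c = np.full((K, K), mean - contrast * n_boost / (E - n_boost))
        c[boost] = mean + contrast
        np.fill_diagonal(c, 1.0)
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("requested state means/contrast are not positive definite")
        return c

    return [build(weak_mean, within_primary), build(strong_mean, within_assoc)]


def constant_correlation(k: int, r: float) -> np.ndarray:
    """K x K constant-correlation matrix with unit diagonal.

    Positive definite for -1/(k-1) < r < 1.
    """
    if not (-1.0 / (k - 1) < r < 1.0):
        raise ValueError(f"off-diagonal r={r} not positive definite for K={k}")
    c = np.full((k, k), float(r))
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class StateGenParams:
    """Parameters of the hidden-state switching time-series generator.

    Parameters
    ----------
    K : int
        Number of networks (channels), >= 2.
    T : int
        Number of volumes, >= 1.
    tr : float
        Repetition time in seconds (default 0.392, the neonatal
        multiband-EPI protocol this pipeline targets).
    state_cov : list of (K, K) ndarray, optional
        Per-state covariance on the correlation scale: symmetric positive
        definite with unit diagonal.  Defaults to two constant-correlation
        states (off-diagonal 0.1 and 0.45).
    stay_prob : tuple of float
        Per-state self-transition probability per volume, each in [0, 1].
        The default 0.98 at TR = 0.392 s gives mean dwell ~ 19.6 s.
    noise_sd : float
        Additive white observation-noise standard deviation.
    seed : int
        RNG seed; all output is bit-reproducible for a fixed seed.
    """

    K: int = 17
    T: int = 1600
    tr: float = 0.392
    k_true: int = 2
    state_cov: list[np.ndarray] | None = None
    stay_prob: tuple[float, ...] = (0.98, 0.98)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.state_cov is None:
            if self.k_true == 2:
                self.state_cov = two_state_covs(self.K)
            else:
                raise ValueError("state_cov required when k_true != 2")
        self.state_cov = [np.asarray(c, dtype=float) for c in self.state_cov]
        self.k_true = len(self.state_cov)
        if len(self.stay_prob) != self.k_true:
            raise ValueError("stay_prob length must equal number of states")
        for p in self.stay_prob:
            if not (0.0 <= p <= 1.0):
                raise ValueError("stay_prob entries must lie in [0, 1]")
        for c in self.state_cov:
            if c.shape != (self.K, self.K):
                raise ValueError("state_cov shape mismatch")
            if not np.allclose(c, c.T):
                raise ValueError("state covariance must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("state covariance must have unit diagonal")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("state covariance must be positive definite")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic transition matrix: off-diagonal mass spread evenly."""
        k = self.k_true
        P = np.empty((k, k))
        for i, p in enumerate(self.stay_prob):
            P[i] = (1.0 - p) / (k - 1) if k > 1 else 0.0
            P[i, i] = p
        return P

    def stationary_distribution(self) -> np.ndarray:
        P = self.transition_matrix()
        w, v = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class GroundTruth:
    """Planted truth exported by the generators for recovery oracles."""

    state_path: np.ndarray | None = None
    true_occupancy: np.ndarray | None = None
    true_maps: np.ndarray | None = None
    true_betas: dict | None = None
    spike_indices: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def gen_state_path(p: StateGenParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the hidden-state label per volume.

    First-order Markov chain with ``p.transition_matrix()``, initialised
    from its stationary distribution.  Returns int labels in ``0..k_true-1``.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    P = p.transition_matrix()
    if not np.allclose(P.sum(axis=1), 1.0) or (P < 0).any():
        raise ValueError("transition matrix is not row-stochastic")
    pi = p.stationary_distribution()
    path = np.empty(p.T, dtype=np.intp)
    path[0] = rng.choice(p.k_true, p=pi)
    # cumulative rows let us sample each step with one uniform draw
    cum = np.cumsum(P, axis=1)
    u = rng.random(p.T)
    for t in range(1, p.T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def gen_timeseries(
    p: StateGenParams,
    path: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the T x K series: volume t ~ N(0, state_cov[path[t]]) + noise."""
    path = np.asarray(path)
    if path.shape != (p.T,):
        raise ValueError("path length must equal T")
    if rng is None:
        rng = np.random.default_rng(p.seed + 1)
    chol = [np.linalg.cholesky(c) for c in p.state_cov]
    z = rng.standard_normal((p.T, p.K))
    x = np.empty_like(z)
    for s in range(p.k_true):
        sel = path == s
        x[sel] = z[sel] @ chol[s].T
    if p.noise_sd > 0:
        x += p.noise_sd * rng.standard_normal(x.shape)
    return x


def gen_4d(
    maps: np.ndarray,
    series: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Mix spatial maps with time courses into a 4D volume stack.

    Parameters
    ----------
    maps : (K, nx, ny, nz) ndarray
        Spatial maps on a shared voxel grid.
    series : (T, K) ndarray
        Per-network time courses.
    noise_sd : float
        White voxel noise standard deviation.

    Returns
    -------
    (nx, ny, nz, T) ndarray — volume t is sum_k maps[k] * series[t, k] + noise.
    """
    maps = np.asarray(maps, dtype=float)
    series = np.asarray(series, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (K, nx, ny, nz)")
    if series.ndim != 2 or series.shape[1] != maps.shape[0]:
        raise ValueError("series must be (T, K) with K matching maps")
    K = maps.shape[0]
    grid = maps.shape[1:]
    flat = maps.reshape(K, -1)  # K x V
    data = series @ flat  # T x V
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    return np.moveaxis(data.reshape((series.shape[0],) + grid), 0, -1)


def random_maps(
    K: int, grid: tuple[int, int, int] = (8, 8, 8), seed: int = 0, smooth: bool = True
) -> np.ndarray:
    """K random spatial maps on a small voxel grid (fixtures).

    Smoothed zero-mean Gaussian fields: spatially structured but nearly
    mutually uncorrelated, like ICA-derived network maps.
    """
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((K,) + grid)
    if smooth:
        from scipy.ndimage import gaussian_filter

        maps = np.stack([gaussian_filter(m, 1.0) for m in maps])
    return maps


def gen_motion(
    T: int,
    spike_rate: float = 0.02,
    spike_scale: float = 2.0,
    drift_amp: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate T x 6 rigid-body realignment parameters with planted spikes.

    The baseline is a smooth sum of low-frequency sinusoids per channel
    (rotations in radians, columns 0-2; translations in mm, columns 3-5);
    spikes are single-volume displacements drawn Bernoulli(spike_rate) and
    scaled by ``spike_scale`` mm (translations) so the framewise-displacement
    outlier rule can recover them.

    Returns
    -------
    params : (T, 6) ndarray
    spike_indices : ndarray of planted spike volume indices (sorted)
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    params = np.zeros((T, 6))
    for j in range(6):
        amp = drift_amp * (0.02 if j < 3 else 1.0) * (0.5 + rng.random())
        n_cycles = rng.uniform(1.0, 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        params[:, j] = amp * np.sin(2 * np.pi * n_cycles * t / T + phase)
    spikes = np.flatnonzero(rng.random(T - 1) < spike_rate) + 1
    for s in spikes:
        # one-volume jump in a random translation axis
        axis = 3 + rng.integers(3)
        params[s, axis] += spike_scale * rng.choice([-1.0, 1.0])
    return params, spikes


def gen_cohort(
    n_subjects: int,
    effect_spec: dict[tuple[int, int], dict[str, float]] | None = None,
    K: int = 10,
    T: int = 800,
    tr: float = 0.392,
    stay_prob: tuple[float, float] = (0.98, 0.98),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[np.ndarray], GroundTruth]:
    """Generate a synthetic cohort with injected covariate effects.

    Each subject gets a two-state switching series; ``effect_spec`` maps an
    edge ``(i, j)`` to per-covariate slopes, e.g. ``{(0, 1): {"ga": 0.02}}``
    meaning that edge's correlation (in every hidden state) shifts by
    0.02 r-units per week of gestational age relative to the 40.5-week
    cohort midpoint.  Because the shift applies to all states equally, the
    subject's noiseless static FNC edge inherits exactly the injected slope.

    Returns the cohort table (subject, ga_weeks, pna_weeks, pma_weeks, sex,
    group, mean_fd), the list of T x K series, and a :class:`GroundTruth`
    with per-subject state paths, occupancies and the injected betas.
    """
    if n_subjects < 1:
        raise ValueError("empty cohort: n_subjects must be >= 1")
    effect_spec = effect_spec or {}
    rng = np.random.default_rng(seed)
    ga = rng.uniform(37.0, 44.0, n_subjects)
    pna = rng.uniform(0.0, 4.0, n_subjects)
    sex = np.array(["M", "F"])[np.arange(n_subjects) % 2]
    rng.shuffle(sex)
    mean_fd = rng.uniform(0.05, 0.35, n_subjects)
    table = pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n_subjects)],
            "ga_weeks": ga,
            "pna_weeks": pna,
            "pma_weeks": ga + pna,
            "sex": sex,
            "group": "term",
            "mean_fd": mean_fd,
        }
    )

    series_list: list[np.ndarray] = []
    paths = np.empty((n_subjects, T), dtype=np.intp)
    for i in range(n_subjects):
        covs = two_state_covs(K)
        for (a, b), slopes in effect_spec.items():
            delta = 0.0
            delta += slopes.get("ga", 0.0) * (ga[i] - 40.5)
            delta += slopes.get("pna", 0.0) * (pna[i] - 2.0)
            for c in covs:
                c[a, b] += delta
                c[b, a] += delta
        for c in covs:
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(
                    "effect_spec slopes make a state covariance non-positive-"
                    f"definite for subject {i} (GA={ga[i]:.1f} wk); reduce the slope"
                )
        p = StateGenParams(
            K=K, T=T, tr=tr, state_cov=covs, stay_prob=stay_prob,
            noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)),
        )
        path = gen_state_path(p)
        paths[i] = path
        series_list.append(gen_timeseries(p, path))

    occ = np.stack(
        [np.bincount(paths[i], minlength=2) / T for i in range(n_subjects)]
    )
    ref = StateGenParams(K=K, T=T, stay_prob=stay_prob, seed=seed)
    truth = GroundTruth(
        state_path=paths,
        true_occupancy=ref.stationary_distribution(),
        true_betas={edge: dict(sl) for edge, sl in effect_spec.items()},
        extra={"per_subject_occupancy": occ, "ga_center": 40.5, "pna_center": 2.0},
    )
    return table, series_list, truth
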