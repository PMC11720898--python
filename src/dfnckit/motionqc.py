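"""Head-motion quality control for resting-state fMRI.

Framewise displacement (FD) from rigid-body realignment parameters, an
IQR-based motion-outlier rule, selection of the contiguous lowest-motion
segment, and subject-level exclusion.

Conventions: rotations in radians, translations in mm; rotations are
converted to arc length on a 50 mm sphere (the standard head-radius
convention) when summed into FD.  FD of the first volume is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FDSeries",
    "SubjectQC",
    "read_motion_params",
    "compute_fd",
    "detect_outliers",
    "select_segment",
    "qc_subject",
]

DEFAULT_RADIUS_MM = 50.0
DEFAULT_SEGMENT_LENGTH = 1600
MEAN_FD_LIMIT_MM = 0.5
#: maximum tolerated fraction of outlier volumes within the selected segment
OUTLIER_FRACTION_LIMIT = 0.10


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm) and the head radius used."""

    fd: np.ndarray
    radius: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if (self.fd < 0).any():
            raise ValueError("FD must be nonnegative")

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())

    def __len__(self) -> int:
        return self.fd.size


@dataclass
class SubjectQC:
    """Subject-level motion QC summary."""

    mean_fd: float
    outlier_mask: np.ndarray
    n_outliers: int
    segment_start: int
    segment_length: int
    n_outliers_in_segment: int
    excluded: bool
    reason: str | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "mean_fd": self.mean_fd,
                "n_outliers": self.n_outliers,
                "segment_start": self.segment_start,
                "segment_length": self.segment_length,
                "n_outliers_in_segment": self.n_outliers_in_segment,
                "excluded": self.excluded,
                "reason": self.reason,
            }
        )


def read_motion_params(
    path, rotations_first: bool = True, degrees: bool = False
) -> np.ndarray:
    """Read a 6-column realignment-parameter file.

    Whitespace- or comma-delimited, one row per volume.  Returns a (T, 6)
    array ordered (rot_x, rot_y, rot_z, trans_x, trans_y, trans_z) with
    rotations in radians.  ``rotations_first=False`` flips the column
    blocks for realignment outputs that store translations first;
    ``degrees=True`` converts rotation columns from degrees.
    """
    try:
        m = np.loadtxt(path)
    except ValueError:
        m = np.loadtxt(path, delimiter=",")
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {m.shape[1]}")
    if not rotations_first:
        m = np.hstack([m[:, 3:], m[:, :3]])
    if degrees:
        m = m.copy()
        m[:, :3] = np.deg2rad(m[:, :3])
    return m


def compute_fd(params: np.ndarray, radius: float = DEFAULT_RADIUS_MM) -> FDSeries:
    """Power framewise displacement from (T, 6) realignment parameters.

    FD[t] = sum_i |Delta trans_i[t]| + radius * sum_j |Delta rot_j[t]| with
    rotations (radians, columns 0-2) converted to mm of arc on a sphere of
    the given radius; FD[0] = 0 by convention.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("params must be (T, 6)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes for FD")
    if not np.isfinite(params).all():
        raise ValueError("non-finite motion parameters")
    diff = np.abs(np.diff(params, axis=0))
    fd = radius * diff[:, :3].sum(axis=1) + diff[:, 3:].sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]), radius=radius)


def detect_outliers(fd: FDSeries | np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Boolean mask of motion-outlier volumes.

    A volume is an outlier when its FD strictly exceeds
    Q75 + multiplier * IQR, quantiles by linear interpolation over the
    whole series.  With zero spread the threshold equals the common value
    and nothing is flagged.
    """
    values = fd.fd if isinstance(fd, FDSeries) else np.asarray(fd, dtype=float)
    if values.size == 0:
        raise ValueError("empty FD series")
    q25, q75 = np.percentile(values, [25, 75])
    return values > q75 + multiplier * (q75 - q25)


def select_segment(mask: np.ndarray, length: int = DEFAULT_SEGMENT_LENGTH) -> int:
    """Start index of the contiguous window of ``length`` volumes with the
    fewest outliers; ties broken by the earliest start.  One pass, running sum.
    """
    mask = np.asarray(mask, dtype=bool)
    T = mask.size
    if length < 1:
        raise ValueError("length must be >= 1")
    if T < length:
        raise ValueError(
            f"subject has only {T} volumes but a {length}-volume segment is required"
        )
    counts = np.convolve(mask.astype(np.intp), np.ones(length, dtype=np.intp), "valid")
    return int(np.argmin(counts))  # argmin takes the first minimum -> earliest start


def qc_subject(
    fd: FDSeries,
    mask: np.ndarray | None = None,
    length: int = DEFAULT_SEGMENT_LENGTH,
    mean_fd_limit: float = MEAN_FD_LIMIT_MM,
    outlier_fraction_limit: float = OUTLIER_FRACTION_LIMIT,
) -> SubjectQC:
    """Full subject QC: outlier detection, segment selection, exclusion.

    A subject is excluded when the selected segment contains more than
    ``outlier_fraction_limit * length`` outlier volumes (default: >160 of
    1600) or the mean FD over the full series exceeds ``mean_fd_limit``
    (default 0.5 mm).  The outlier threshold is computed on the full
    series; the count criterion is evaluated within the selected segment.
    """
    if mask is None:
        mask = detect_outliers(fd)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(fd):
        raise ValueError("mask and FD series lengths differ")
    start = select_segment(mask, length)
    in_seg = int(mask[start : start + length].sum())
    mean_fd = fd.mean_fd

    excluded, reason = False, None
    if in_seg > outlier_fraction_limit * length:
        excluded, reason = True, "outlier_count"
    elif mean_fd > mean_fd_limit:
        excluded, reason = True, "mean_fd"
    return SubjectQC(
        mean_fd=mean_fd,
        outlier_mask=mask,
        n_outliers=int(mask.sum()),
        segment_start=start,
        segment_length=length,
        n_outliers_in_segment=in_seg,
        excluded=excluded,
        reason=reason,
    )
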