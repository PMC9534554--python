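"""Time-series preprocessing for movie-watching fMRI.

Implements the temporal stages of a standard naturalistic-fMRI
preprocessing chain: initial-volume trimming, framewise displacement
(FD) and frame censoring, subject-level motion exclusion, linear
detrending, band-pass filtering, nuisance regression, and ROI/network
time-course extraction.  Spatial preprocessing (realignment estimation,
normalisation, smoothing, segmentation) is assumed done upstream; this
module consumes its outputs (motion parameters, voxel time series,
parcellation labels).

The canonical order is: trim -> FD/censor -> detrend -> bandpass ->
nuisance regression -> extraction.  Censored frames are masked, never
deleted, so frame indices stay aligned across subjects — a requirement
for inter-subject correlation, which pairs frames across subjects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_TRANS_LIMIT_MM = 2.5
DEFAULT_ROT_LIMIT_DEG = 2.5
DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass
class SubjectTimeSeries:
    """Per-subject network-seed and thalamic-voxel time courses.

    Attributes
    ----------
    subject_id : str
    network_ts : (T, K) array
        One mean time course per cortical network.
    thal_ts : (T, V) array
        One time course per thalamic voxel.
    frame_mask : (T,) bool array
        True for retained frames.  Censoring flips entries to False;
        the matrices themselves are untouched.
    voxel_coords : (V, 3) int array
        0-based integer grid coordinates of the thalamic voxels.
    tr : float
        Repetition time in seconds.
    """

    subject_id: str
    network_ts: np.ndarray
    thal_ts: np.ndarray
    frame_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_coords: np.ndarray = field(default=None)  # type: ignore[assignment]
    tr: float = 2.47

    def __post_init__(self) -> None:
        self.network_ts = np.asarray(self.network_ts, dtype=float)
        self.thal_ts = np.asarray(self.thal_ts, dtype=float)
        if self.network_ts.ndim != 2 or self.thal_ts.ndim != 2:
            raise ValueError("time-series matrices must be 2-D (frames x columns)")
        if self.network_ts.shape[0] != self.thal_ts.shape[0]:
            raise ValueError(
                f"network_ts and thal_ts disagree on frame count: "
                f"{self.network_ts.shape[0]} vs {self.thal_ts.shape[0]}"
            )
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.n_frames, dtype=bool)
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
        if self.frame_mask.shape != (self.n_frames,):
            raise ValueError("frame_mask length must equal the frame count")
        if self.voxel_coords is None:
            self.voxel_coords = default_voxel_coords(self.n_voxels)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.shape != (self.n_voxels, 3):
            raise ValueError("voxel_coords must be (V, 3)")
        if len(np.unique(self.voxel_coords, axis=0)) != self.n_voxels:
            raise ValueError("voxel_coords must be unique per voxel")

    @property
    def n_frames(self) -> int:
        return self.network_ts.shape[0]

    @property
    def n_networks(self) -> int:
        return self.network_ts.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.thal_ts.shape[1]


def default_voxel_coords(n_voxels: int) -> np.ndarray:
    """Compact contiguous grid coordinates for ``n_voxels`` voxels.

    Fills a near-cubic box in C order, so runs of consecutive voxel
    indices form face-connected components — a convenient stand-in for
    the thalamus when no real mask geometry is supplied.
    """
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nz = side
    ny = side
    nx = int(np.ceil(n_voxels / (ny * nz)))
    coords = np.argwhere(np.ones((nx, ny, nz), dtype=bool))
    return coords[:n_voxels]


def trim_initial_volumes(sts: SubjectTimeSeries, n: int = 5) -> SubjectTimeSeries:
    """Drop the first ``n`` frames (dummy scans before field stabilisation)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if sts.n_frames <= n:
        raise ValueError(f"cannot trim {n} frames from a series of {sts.n_frames}")
    return replace(
        sts,
        network_ts=sts.network_ts[n:],
        thal_ts=sts.thal_ts[n:],
        frame_mask=sts.frame_mask[n:],
    )


def trim_matrix(ts: np.ndarray, n: int = 5) -> np.ndarray:
    """Matrix form of :func:`trim_initial_volumes` for bare arrays."""
    ts = np.asarray(ts)
    if ts.shape[0] <= n:
        raise ValueError(f"cannot trim {n} frames from a series of {ts.shape[0]}")
    return ts[n:]


def framewise_displacement(
    motion: np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement (Power formulation) from a (T, 6) motion trace.

    Columns are translations x, y, z in mm followed by rotations pitch,
    roll, yaw in radians.  FD(t) is the sum of absolute backward
    differences of the translations plus ``head_radius`` times the sum
    of absolute rotation differences (arc length on a sphere of that
    radius).  FD at the first frame is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def mean_fd(fd: np.ndarray) -> float:
    """Mean framewise displacement (mFD), the per-subject motion summary."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    return float(fd.mean())


def censor_frames(
    sts: SubjectTimeSeries,
    fd: np.ndarray,
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
) -> SubjectTimeSeries:
    """Mask out frames whose FD strictly exceeds ``threshold`` (mm).

    Masking is logical: matrices keep their shape so frame indices stay
    aligned across subjects; correlation code honours the mask.
    """
    if threshold <= 0:
        raise ValueError("censoring threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (sts.n_frames,):
        raise ValueError("FD series length must equal the frame count")
    keep = fd <= threshold
    n_censored = int((~keep & sts.frame_mask).sum())
    if n_censored:
        logger.info("CENSOR subject=%s frames=%d", sts.subject_id, n_censored)
    return replace(sts, frame_mask=sts.frame_mask & keep)


def subject_motion_exclusion(
    motion: np.ndarray,
    trans_limit: float = DEFAULT_TRANS_LIMIT_MM,
    rot_limit_deg: float = DEFAULT_ROT_LIMIT_DEG,
) -> bool:
    """True if the subject should be excluded for excessive head movement.

    Exclusion when any |translation| > ``trans_limit`` mm or any
    |rotation| > ``rot_limit_deg`` degrees (strict inequalities;
    rotations stored in radians are converted for the check).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    max_trans = np.abs(motion[:, :3]).max() if motion.size else 0.0
    max_rot_deg = np.degrees(np.abs(motion[:, 3:]).max()) if motion.size else 0.0
    return bool(max_trans > trans_limit or max_rot_deg > rot_limit_deg)


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove each column's least-squares line (intercept + slope)."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 frames to detrend")
    return signal.detrend(ts, axis=0, type="linear")


def bandpass(
    ts: np.ndarray,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
    tr: float = 2.47,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    A second-order Butterworth band-pass applied forward and backward
    (``filtfilt``), squaring the magnitude response and cancelling phase
    delay.  Columns are demeaned first; DC is outside the passband by
    construction.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 0.5 / tr
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz is not below the Nyquist frequency "
            f"{nyquist:.4f} Hz at TR {tr} s"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=1.0 / tr, output="sos")
    demeaned = ts - ts.mean(axis=0, keepdims=True)
    return signal.sosfiltfilt(sos, demeaned, axis=0)


def build_motion_regressors(motion: np.ndarray) -> np.ndarray:
    """The 12 motion regressors: 6 parameters and their backward differences.

    The first row of each derivative column is 0 (no preceding frame).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames for motion derivatives")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    return np.hstack([motion, deriv])


def regress_nuisance(ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """OLS residual of each column after projecting out [intercept | nuisance].

    Zero-variance or linearly dependent nuisance columns are dropped
    with a logged warning; the projection itself is computed by
    least squares, so residuals are orthogonal to every retained
    regressor.
    """
    ts = np.asarray(ts, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != ts.shape[0]:
        raise ValueError("nuisance and data frame counts differ")
    if not np.all(np.isfinite(nuisance)):
        raise ValueError("nuisance regressors contain non-finite values")
    t, r = ts.shape[0], nuisance.shape[1]
    if t <= r + 1:
        raise ValueError(f"need more frames ({t}) than regressors + 1 ({r + 1})")

    keep = nuisance.std(axis=0) > 0
    if not keep.all():
        logger.warning("NUISANCE dropped %d zero-variance column(s)", int((~keep).sum()))
    x = np.column_stack([np.ones(t), nuisance[:, keep]])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        logger.warning(
            "NUISANCE rank-deficient design (rank %d of %d); lstsq minimum-norm fit",
            rank, x.shape[1],
        )
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    return ts - x @ beta


def extract_network_timecourses(
    voxel_ts: np.ndarray,
    roi_labels: np.ndarray,
    membership: "dict[int, str] | object",
) -> "tuple[np.ndarray, list[str]]":
    """Average voxels into ROI courses, then ROIs into network courses.

    Parameters
    ----------
    voxel_ts : (T, N) array of cortical voxel time courses.
    roi_labels : length-N integer ROI id per voxel.
    membership : mapping roi_id -> network name, or a DataFrame with
        columns ``roi_id`` and ``network_name``.

    Returns
    -------
    (T, K) array of network courses and the list of network names, in
    order of first appearance in the membership table.
    """
    import pandas as pd

    voxel_ts = np.asarray(voxel_ts, dtype=float)
    roi_labels = np.asarray(roi_labels)
    if roi_labels.shape[0] != voxel_ts.shape[1]:
        raise ValueError("one ROI label per voxel column is required")
    if isinstance(membership, pd.DataFrame):
        pairs = list(zip(membership["roi_id"], membership["network_name"]))
    else:
        pairs = list(membership.items())

    networks: dict[str, list[np.ndarray]] = {}
    for roi_id, network in pairs:
        in_roi = roi_labels == roi_id
        if not in_roi.any():
            raise ValueError(f"ROI {roi_id!r} has no voxels")
        networks.setdefault(str(network), []).append(voxel_ts[:, in_roi].mean(axis=1))
    unknown = set(np.unique(roi_labels)) - {roi for roi, _ in pairs}
    if unknown:
        raise ValueError(f"voxel labels not in membership table: {sorted(unknown)}")
    names = list(networks)
    if not names:
        raise ValueError("membership table defines no networks")
    courses = np.column_stack([np.mean(networks[name], axis=0) for name in names])
    return courses, names


def preprocess_subject(
    sts: SubjectTimeSeries,
    motion: np.ndarray,
    extra_nuisance: "np.ndarray | None" = None,
    *,
    trim: int = 5,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    band: "tuple[float, float] | None" = DEFAULT_BAND_HZ,
) -> "tuple[SubjectTimeSeries, float]":
    """Run the full temporal chain on one subject; returns (series, mFD).

    Order: trim -> FD/censor -> detrend -> bandpass -> nuisance
    regression.  Nuisance regressors (12 motion-derived columns plus any
    extra channels such as WM/CSF means) are band-pass filtered exactly
    like the data before regression so the projection cannot reintroduce
    out-of-band variance.  mFD is computed on post-trim frames.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != sts.n_frames:
        raise ValueError("motion trace and time series disagree on frame count")
    sts = trim_initial_volumes(sts, trim)
    motion = trim_matrix(motion, trim) if trim else motion
    fd = framewise_displacement(motion, head_radius)
    mfd = mean_fd(fd)
    sts = censor_frames(sts, fd, fd_threshold)

    def chain(ts: np.ndarray) -> np.ndarray:
        ts = detrend_linear(ts)
        if band is not None:
            ts = bandpass(ts, band[0], band[1], tr=sts.tr)
        return ts

    nuis = build_motion_regressors(motion)
    if extra_nuisance is not None:
        extra = trim_matrix(np.asarray(extra_nuisance, dtype=float), trim)
        nuis = np.hstack([nuis, extra])
    nuis = chain(nuis)
    network_ts = regress_nuisance(chain(sts.network_ts), nuis)
    thal_ts = regress_nuisance(chain(sts.thal_ts), nuis)
    return replace(sts, network_ts=network_ts, thal_ts=thal_ts), mfd
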