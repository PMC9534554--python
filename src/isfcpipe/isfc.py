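"""Leave-one-out inter-subject functional correlation (ISFC).

The central statistic: within each age group, each subject's K network
seed courses are correlated against every OTHER group member's V
thalamic voxel courses (Pearson, over jointly retained frames), the
n-1 pairwise K x V matrices are averaged, and the result is Fisher
r-to-z transformed.  Because the seed and target come from different
subjects, intrinsic dynamics and scanner noise — independent across
people — cancel, leaving stimulus-locked coupling.

Also provides age binning, group means, and the one-sample-t + FDR
analysis mask applied before any regression modelling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FISHER_EPS = 1e-7
MIN_JOINT_FRAMES = 10
VALID_BIN_WIDTHS = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class AgeGroup:
    group_id: int
    lo: int
    hi: int
    subject_ids: tuple

    @property
    def n(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class AgeGroupSpec:
    bin_width: int
    anchor: int
    groups: tuple

    def group_of(self, subject_id: str) -> AgeGroup:
        for g in self.groups:
            if subject_id in g.subject_ids:
                return g
        raise KeyError(subject_id)


def bin_by_age(cohort: pd.DataFrame, width: int = 10,
               anchor: "int | None" = None) -> AgeGroupSpec:
    """Partition subjects into contiguous age bins of ``width`` years.

    Subject with age a joins bin floor((a - anchor) / width); the last
    bin is truncated at the sample maximum.  Bins containing fewer than
    2 subjects cannot support leave-one-out ISFC and raise an error
    naming them.
    """
    if width not in VALID_BIN_WIDTHS:
        raise ValueError(f"bin width must be one of {VALID_BIN_WIDTHS}, got {width}")
    ages = cohort["age"].to_numpy()
    if anchor is None:
        anchor = int(ages.min())
    if np.any(ages < anchor):
        raise ValueError("all ages must be >= the bin anchor")
    idx = ((ages - anchor) // width).astype(int)
    max_age = int(ages.max())
    groups = []
    bad = []
    for b in range(idx.max() + 1):
        members = cohort.loc[idx == b, "subject_id"].tolist()
        lo = anchor + b * width
        hi = min(lo + width - 1, max_age)
        if len(members) < 2:
            bad.append((lo, hi, len(members)))
        groups.append(AgeGroup(group_id=b, lo=lo, hi=hi,
                               subject_ids=tuple(members)))
    if bad:
        raise ValueError(
            "age bins with fewer than 2 subjects cannot be used for ISFC: "
            + ", ".join(f"{lo}-{hi} (n={n})" for lo, hi, n in bad)
        )
    return AgeGroupSpec(bin_width=width, anchor=anchor, groups=tuple(groups))


def _standardize(ts: np.ndarray) -> "tuple[np.ndarray, np.ndarray]":
    """Column-demean and L2-normalise; returns (unit matrix, zero-var flags)."""
    centered = ts - ts.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return centered / safe, zero


def pairwise_isfc(
    seed_network_ts: np.ndarray,
    target_thal_ts: np.ndarray,
    joint_mask: "np.ndarray | None" = None,
) -> np.ndarray:
    """Pearson r between one subject's K seeds and another's V voxels.

    Computed over jointly retained frames only.  Entries involving a
    zero-variance column are set to NaN (missing) and counted in the
    log.  Fewer than 10 joint frames is an error.
    """
    y = np.asarray(seed_network_ts, dtype=float)
    x = np.asarray(target_thal_ts, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("seed and target must share the frame clock")
    if joint_mask is not None:
        joint_mask = np.asarray(joint_mask, dtype=bool)
        y, x = y[joint_mask], x[joint_mask]
    if y.shape[0] < MIN_JOINT_FRAMES:
        raise ValueError(
            f"only {y.shape[0]} jointly retained frames; need >= {MIN_JOINT_FRAMES}"
        )
    yu, y_zero = _standardize(y)
    xu, x_zero = _standardize(x)
    r = yu.T @ xu
    if y_zero.any() or x_zero.any():
        r[y_zero, :] = np.nan
        r[:, x_zero] = np.nan
        logger.info("PAIRWISE zero-variance columns: %d seed, %d target",
                    int(y_zero.sum()), int(x_zero.sum()))
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: "float | np.ndarray") -> "float | np.ndarray":
    """Variance-stabilising Fisher transform z = atanh(r).

    |r| is clipped to 1 - 1e-7 first so degenerate perfect correlations
    stay finite; |r| > 1 is an error.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr) > 1.0 + 1e-12):
            raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))
    z = np.where(np.isnan(arr), np.nan, z)
    return float(z) if np.isscalar(r) else z


@dataclass
class ISFCMatrix:
    """One subject's Fisher-z ISFC matrix and its provenance."""

    subject_id: str
    group_id: int
    values: np.ndarray          # (K, V), z scale
    n_pairs: int                # group size - 1
    scale: str = "z"
    pair_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pair_counts is None:
            self.pair_counts = np.full(self.values.shape, self.n_pairs, dtype=int)


def subject_isfc(
    i: int,
    group_series: "list",
    symmetrize: bool = False,
) -> ISFCMatrix:
    """Leave-one-out ISFC matrix for subject ``i`` of a group.

    ``group_series`` is the list of the group's SubjectTimeSeries.  The
    subject's network seeds are correlated against each other member's
    thalamic voxels; the n-1 pairwise r-matrices are averaged
    element-wise (missing entries excluded, with count tracking) and
    Fisher z applied.  With ``symmetrize`` the reverse direction
    (others' seeds vs subject i's voxels) is averaged in as well — off
    by default, matching the seed/target asymmetry of the construction.
    """
    n = len(group_series)
    if n < 2:
        raise ValueError("group must have at least 2 subjects")
    me = group_series[i]
    mats = []
    for j, other in enumerate(group_series):
        if j == i:
            continue
        joint = me.frame_mask & other.frame_mask
        r = pairwise_isfc(me.network_ts, other.thal_ts, joint)
        if symmetrize:
            r_rev = pairwise_isfc(other.network_ts, me.thal_ts, joint)
            r = (r + r_rev) / 2.0
        mats.append(r)
    stack = np.stack(mats)
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(stack, axis=0)
    mean_r[counts == 0] = np.nan
    return ISFCMatrix(
        subject_id=me.subject_id,
        group_id=-1,
        values=fisher_z(mean_r),
        n_pairs=n - 1,
        pair_counts=counts,
    )


def group_isfc(
    group: AgeGroup,
    series_by_id: "dict[str, object]",
    symmetrize: bool = False,
) -> "list[ISFCMatrix]":
    """Leave-one-out ISFC matrices for every subject of one age group."""
    members = [series_by_id[sid] for sid in group.subject_ids]
    low_frames = [m.subject_id for m in members if m.frame_mask.mean() < 0.5]
    if low_frames:
        logger.warning("GROUP %d: >50%% frames censored for %s",
                       group.group_id, low_frames)
    out = []
    for i in range(len(members)):
        m = subject_isfc(i, members, symmetrize=symmetrize)
        m.group_id = group.group_id
        out.append(m)
    return out


def cohort_isfc(
    spec: AgeGroupSpec,
    series_by_id: "dict[str, object]",
    symmetrize: bool = False,
) -> "list[ISFCMatrix]":
    """ISFC matrices for all subjects, grouped per the age-bin spec."""
    out = []
    for group in spec.groups:
        out.extend(group_isfc(group, series_by_id, symmetrize=symmetrize))
    return out


def group_mean_isfc(matrices: "list[ISFCMatrix]") -> np.ndarray:
    """Element-wise mean (z scale) over subjects' ISFC matrices."""
    if not matrices:
        raise ValueError("need at least one ISFC matrix")
    stack = np.stack([m.values for m in matrices])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def significance_mask(
    matrices: "list[ISFCMatrix]",
    q: float = 0.05,
    min_valid_frac: float = 0.8,
) -> "tuple[np.ndarray, np.ndarray]":
    """Edges with group-level ISFC significantly nonzero, pooling all subjects.

    Per edge: one-sample t of the subjects' z values against 0
    (two-sided, df = n_valid - 1), then Benjamini-Hochberg FDR at level
    ``q`` across the whole K x V family.  Returns (mask, t_values).
    Edges missing in more than ``1 - min_valid_frac`` of subjects, or
    identically zero, are excluded.  A zero-variance edge with nonzero
    mean is an exact effect (p = 0, rejected).
    """
    stack = np.stack([m.values for m in matrices])  # (S, K, V)
    n_subj = stack.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects for the one-sample t-test")
    valid = ~np.isnan(stack)
    n_valid = valid.sum(axis=0)
    eligible = n_valid >= max(3, int(np.ceil(min_valid_frac * n_subj)))
    n_dropped = int((~eligible).sum())
    if n_dropped:
        logger.info("MASK dropped %d edges missing in > %.0f%% of subjects",
                    n_dropped, 100 * (1 - min_valid_frac))

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)

    t_vals = np.full(mean.shape, np.nan)
    p_vals = np.full(mean.shape, np.nan)
    ok = eligible & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals[ok] = mean[ok] / (sd[ok] / np.sqrt(n_valid[ok]))
    p_vals[ok] = 2.0 * stats.t.sf(np.abs(t_vals[ok]), df=n_valid[ok] - 1)
    exact = eligible & (sd == 0) & (mean != 0)
    p_vals[exact] = 0.0
    t_vals[exact] = np.inf * np.sign(mean[exact])
    degenerate = eligible & (sd == 0) & (mean == 0)

    testable = eligible & ~degenerate
    mask = np.zeros(mean.shape, dtype=bool)
    if testable.any():
        reject, _, _, _ = multipletests(p_vals[testable], alpha=q, method="fdr_bh")
        mask[testable] = reject
    return mask, t_vals


def bh_qvalues(p: np.ndarray, q: float = 0.05) -> "tuple[np.ndarray, np.ndarray]":
    """Benjamini-Hochberg step-up: returns (monotone q-values, reject flags)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject
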