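"""Synthetic multi-subject movie-fMRI cohorts with known thalamo-cortical coupling.

Generates everything the downstream analysis consumes — a cohort table
(age, sex, education, brain volume, fluid intelligence), stimulus-locked
network-seed and thalamic-voxel time series, and head-motion traces —
from an explicit generative model whose expected inter-subject
functional correlation (ISFC) has a closed form, so every analysis stage
can be checked against ground truth.

Generative model
----------------
A single stimulus signal set ``s_k(t)`` (one unit-variance course per
cortical network, shared by all subjects — everyone watches the same
movie) drives both sides of each edge.  For subject ``i`` with age
``age_i``::

    network seed   y_k(t) = sqrt(c_k)      * s_k(t)     + sqrt(b) * g_i(t) + sqrt(1 - c_k - b)      * eps_k(t)
    thalamic voxel x_v(t) = sqrt(a_v(age)) * s_{k(v)}(t) + sqrt(b) * g_i(t) + sqrt(1 - a_v - b)      * eta_v(t)

``g_i`` is a subject-specific intrinsic signal shared across that
subject's regions; ``eps``/``eta`` are independent white noises.  All
components have unit variance, so the cross-SUBJECT correlation between
subject i's network k and subject j's voxel v is ``sqrt(c_k * a_v(age_j))``
when ``k == k(v)`` and 0 otherwise — intrinsic signal and noise are
independent across subjects and drop out, which is the rationale for
inter-subject (rather than within-subject) correlation.

The voxel coupling fraction ``a_v(age)`` is a clipped quadratic in
standardised age, ``u = (age - age_center) / age_scale``, giving the
generator a controllable, ground-truth age effect per voxel.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import SubjectTimeSeries, default_voxel_coords

COUPLING_CLIP = (0.0, 0.95)

# fixed stream ids for seed splitting (one global seed -> per-stage rngs)
_STREAMS = {"cohort": 0, "stimulus": 1, "subject": 2, "motion": 3, "misc": 4}


def stream_rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    """Deterministic child generator for a named stage and integer key.

    A single pipeline seed is expanded through ``SeedSequence`` spawn
    keys, so any stage (or any one subject's stream) can be regenerated
    in isolation and independently of execution order.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], *key))
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort and acquisition parameters for the synthetic generator.

    Defaults mirror the adult-lifespan movie-watching study conditions:
    ages 18-87, 17 network seeds x 620 thalamic voxels, T=193 retained
    frames at TR 2.47 s, and fluid intelligence (Cattell, 0-46 points)
    declining roughly 0.23 points/year.
    """

    n_subjects: int = 100
    age_range: tuple = (18, 87)
    sex_balance: float = 0.5          # fraction male
    education_mean: float = 20.6      # years (age completing full-time education)
    education_sd: float = 3.5
    fi_intercept: float = 43.2        # Cattell points at age 0 (linear model)
    fi_slope: float = -0.23           # points/year
    fi_noise_sd: float = 5.4          # residual sd; gives age-FI r ~ -0.65
    fi_range: tuple = (0.0, 46.0)     # Cattell test score range
    brain_volume_mean: float = 1.40e6  # mm^3
    brain_volume_sd: float = 1.2e5
    n_networks: int = 17
    n_voxels: int = 620
    n_frames: int = 193
    tr: float = 2.47
    intrinsic_loading: float = 0.1    # b: variance share of subject-specific signal
    stimulus_ar: float = 0.0          # AR(1) coefficient for stimulus smoothing
    motion_step_mm: float = 0.02      # random-walk step sd, translations
    motion_step_rad: float = 4e-4     # random-walk step sd, rotations
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.n_networks < 1 or self.n_voxels < 1:
            raise ValueError("need at least one network and one voxel")
        if not 0 <= self.intrinsic_loading < 1:
            raise ValueError("intrinsic_loading must be in [0, 1)")
        if not 0 <= self.sex_balance <= 1:
            raise ValueError("sex_balance must be in [0, 1]")


@dataclass(frozen=True)
class CouplingModel:
    """Ground-truth stimulus coupling for networks and thalamic voxels.

    ``network_coupling[k]`` is the fixed variance fraction ``c_k`` of the
    stimulus in network seed k.  Each voxel v belongs to exactly one
    network ``voxel_assignment[v]`` and couples to that network's
    stimulus with an age-dependent fraction::

        a_v(age) = clip(theta0 + theta1*u + theta2*u**2, 0, 0.95),
        u = (age - age_center) / age_scale
    """

    network_coupling: np.ndarray        # (K,) in [0, 1)
    voxel_assignment: np.ndarray        # (V,) int network index per voxel
    theta: np.ndarray                   # (V, 3) polynomial coefficients
    age_center: float = 52.0
    age_scale: float = 17.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "network_coupling",
                           np.asarray(self.network_coupling, dtype=float))
        object.__setattr__(self, "voxel_assignment",
                           np.asarray(self.voxel_assignment, dtype=int))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        k = self.network_coupling.shape[0]
        if np.any(self.network_coupling < 0) or np.any(self.network_coupling >= 1):
            raise ValueError("network coupling fractions must lie in [0, 1)")
        if self.theta.shape != (self.voxel_assignment.shape[0], 3):
            raise ValueError("theta must be (V, 3)")
        if np.any(self.voxel_assignment < 0) or np.any(self.voxel_assignment >= k):
            raise ValueError("every voxel must be assigned to one existing network")

    @property
    def n_networks(self) -> int:
        return self.network_coupling.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.voxel_assignment.shape[0]

    def coupling_profile(self, age: float) -> np.ndarray:
        """Vector a_v(age) over all voxels, clipped to [0, 0.95]."""
        u = (float(age) - self.age_center) / self.age_scale
        raw = self.theta[:, 0] + self.theta[:, 1] * u + self.theta[:, 2] * u * u
        return np.clip(raw, *COUPLING_CLIP)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in d.items()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CouplingModel":
        d = json.loads(text)
        return cls(**d)


def coupling_strength(age: float, v: int, model: CouplingModel) -> float:
    """Ground-truth stimulus-variance fraction a_v(age) for one voxel."""
    return float(model.coupling_profile(age)[v])


def block_assignment(n_voxels: int, n_networks: int) -> np.ndarray:
    """Contiguous equal blocks of voxels per network.

    Consecutive voxel indices (hence spatially compact regions under the
    default C-order coordinates) share a network, loosely mimicking
    thalamic territories that project to distinct cortical systems.
    """
    return np.minimum((np.arange(n_voxels) * n_networks) // n_voxels,
                      n_networks - 1)


def constant_coupling_model(
    n_networks: int,
    n_voxels: int,
    network_coupling: float = 0.25,
    voxel_coupling: float = 0.25,
    age_center: float = 52.0,
    age_scale: float = 17.0,
) -> CouplingModel:
    """Age-invariant coupling, voxels in contiguous blocks per network."""
    theta = np.zeros((n_voxels, 3))
    theta[:, 0] = voxel_coupling
    return CouplingModel(
        network_coupling=np.full(n_networks, network_coupling),
        voxel_assignment=block_assignment(n_voxels, n_networks),
        theta=theta,
        age_center=age_center,
        age_scale=age_scale,
    )


def age_effect_model(
    n_networks: int,
    n_voxels: int,
    effect_voxels: np.ndarray,
    *,
    network_coupling: float = 0.25,
    null_coupling: float = 0.4,
    coupling_young: float = 0.6,
    coupling_old: float = 0.2,
    quadratic_drop: "float | None" = None,
    age_range: tuple = (18, 87),
    age_center: float = 52.0,
    age_scale: float = 17.0,
) -> CouplingModel:
    """Coupling model with ground-truth age effects on designated voxels.

    Null voxels keep a constant coupling ``null_coupling``.  Effect
    voxels either decline linearly from ``coupling_young`` at the
    youngest age to ``coupling_old`` at the oldest (default), or — when
    ``quadratic_drop`` is given — follow a pure concave profile
    ``peak - quadratic_drop * u**2`` with no linear term.
    """
    effect_voxels = np.asarray(effect_voxels, dtype=int)
    theta = np.zeros((n_voxels, 3))
    theta[:, 0] = null_coupling
    u_lo = (age_range[0] - age_center) / age_scale
    u_hi = (age_range[1] - age_center) / age_scale
    if quadratic_drop is None:
        slope = (coupling_old - coupling_young) / (u_hi - u_lo)
        theta[effect_voxels, 0] = coupling_young - slope * u_lo
        theta[effect_voxels, 1] = slope
    else:
        theta[effect_voxels, 0] = coupling_young
        theta[effect_voxels, 1] = 0.0
        theta[effect_voxels, 2] = -abs(quadratic_drop)
    return CouplingModel(
        network_coupling=np.full(n_networks, network_coupling),
        voxel_assignment=block_assignment(n_voxels, n_networks),
        theta=theta,
        age_center=age_center,
        age_scale=age_scale,
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Ages are uniform integers over the configured range; fluid
    intelligence is linear in age plus Gaussian noise, clipped to the
    Cattell range [0, 46]; sex is Bernoulli(sex_balance) coded 1=male;
    education and brain volume are Gaussian.  Deterministic given the
    config seed.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects (ISFC pairs subjects)")
    rng = stream_rng(config.seed, "cohort")
    n = config.n_subjects
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    sex = (rng.random(n) < config.sex_balance).astype(int)
    education = rng.normal(config.education_mean, config.education_sd, size=n)
    education = np.clip(education, 5.0, None)
    volume = rng.normal(config.brain_volume_mean, config.brain_volume_sd, size=n)
    fi = (config.fi_intercept + config.fi_slope * age
          + rng.normal(0.0, config.fi_noise_sd, size=n))
    fi = np.clip(fi, *config.fi_range)
    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education_years": np.round(education, 2),
        "brain_volume": np.round(volume, 1),
        "fluid_intelligence": np.round(fi, 2),
    })


@dataclass(frozen=True)
class StimulusSet:
    """Shared stimulus-locked signals, one unit-variance course per network."""

    signals: np.ndarray  # (T, K), columns standardised
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.signals.ndim != 2:
            raise ValueError("signals must be (T, K)")


def generate_stimulus(config: CohortConfig) -> StimulusSet:
    """White (optionally AR(1)-smoothed) Gaussian stimulus signals.

    Columns are standardised to sample mean 0 and sample variance 1
    (ddof=1), which makes the closed-form expected ISFC exact and the
    cross-network expected ISFC zero.
    """
    rng = stream_rng(config.seed, "stimulus")
    s = rng.standard_normal((config.n_frames, config.n_networks))
    if config.stimulus_ar:
        phi = config.stimulus_ar
        for t in range(1, s.shape[0]):
            s[t] = phi * s[t - 1] + np.sqrt(1 - phi * phi) * s[t]
    s = (s - s.mean(axis=0)) / s.std(axis=0, ddof=1)
    return StimulusSet(signals=s, seed=config.seed)


def generate_subject_data(
    subject_index: int,
    age: float,
    stimulus: StimulusSet,
    model: CouplingModel,
    config: CohortConfig,
    subject_id: "str | None" = None,
) -> SubjectTimeSeries:
    """Synthesize one subject's network-seed and thalamic-voxel series.

    Implements the generative contract in the module docstring.  Noise
    streams are independent across subjects and deterministic given
    (subject index, config seed).
    """
    t, k = stimulus.signals.shape
    if k != model.n_networks:
        raise ValueError("stimulus and coupling model disagree on network count")
    b = config.intrinsic_loading
    c = model.network_coupling
    a = model.coupling_profile(age)
    if np.any(c + b >= 1.0):
        raise ValueError("variance budget exceeded: c_k + b >= 1 for some network")
    if np.any(a + b >= 1.0):
        raise ValueError("variance budget exceeded: a_v + b >= 1 for some voxel")

    rng = stream_rng(config.seed, "subject", subject_index)
    g = rng.standard_normal((t, 1))
    eps = rng.standard_normal((t, k))
    eta = rng.standard_normal((t, model.n_voxels))

    s = stimulus.signals
    y = np.sqrt(c) * s + np.sqrt(b) * g + np.sqrt(1.0 - c - b) * eps
    s_vox = s[:, model.voxel_assignment]
    x = np.sqrt(a) * s_vox + np.sqrt(b) * g + np.sqrt(1.0 - a - b) * eta
    return SubjectTimeSeries(
        subject_id=subject_id or f"sub-{subject_index:04d}",
        network_ts=y,
        thal_ts=x,
        voxel_coords=default_voxel_coords(model.n_voxels),
        tr=config.tr,
    )


def expected_isfc(
    model: CouplingModel,
    ages_in_group: np.ndarray,
    i: int,
    k: int,
    v: int,
) -> float:
    """Closed-form expected leave-one-out ISFC for one edge.

    Subject i's network-k seed against the other group members' voxel-v
    courses, averaged over pairs: ``sqrt(c_k) * mean_{j != i}
    sqrt(a_v(age_j))`` when k is voxel v's network, else 0.
    """
    ages = np.asarray(ages_in_group, dtype=float)
    if ages.shape[0] < 2:
        raise ValueError("group must have at least 2 subjects")
    if k != model.voxel_assignment[v]:
        return 0.0
    others = np.delete(np.arange(ages.shape[0]), i)
    a_vals = np.array([coupling_strength(ages[j], v, model) for j in others])
    return float(np.sqrt(model.network_coupling[k]) * np.mean(np.sqrt(a_vals)))


def generate_motion_trace(
    subject_index: int,
    config: CohortConfig,
    n_frames: "int | None" = None,
    spikes: "list[tuple[int, int, float]] | None" = None,
) -> np.ndarray:
    """Random-walk head-motion trace, (T, 6): x, y, z mm then rotations rad.

    ``spikes`` is a list of (frame, axis, value) triples added to the
    walk — used to plant known FD excursions or exclusion-level motion.
    Deterministic given (subject index, config seed).
    """
    t = n_frames if n_frames is not None else config.n_frames
    if t < 2:
        raise ValueError("need at least 2 frames")
    rng = stream_rng(config.seed, "motion", subject_index)
    steps = rng.standard_normal((t, 6))
    steps[0] = 0.0
    steps[:, :3] *= config.motion_step_mm
    steps[:, 3:] *= config.motion_step_rad
    trace = np.cumsum(steps, axis=0)
    for frame, axis, value in spikes or []:
        trace[frame, axis] += value
    return trace


def generate_wm_csf(
    subject_index: int, config: CohortConfig, n_frames: "int | None" = None
) -> np.ndarray:
    """Synthetic white-matter and CSF mean signals (two noise channels)."""
    t = n_frames if n_frames is not None else config.n_frames
    rng = stream_rng(config.seed, "misc", subject_index)
    return rng.standard_normal((t, 2))


# ---------------------------------------------------------------------------
# NIfTI fixtures: round-trippable volumes for exercising real-data input mode


def write_fixture_volumes(
    cohort: pd.DataFrame,
    timeseries: "dict[str, SubjectTimeSeries]",
    grid_shape: tuple,
    out_dir: "str | Path",
    rois_per_network: int = 2,
) -> "dict[str, Path]":
    """Write NIfTI volumes + tables such that real-data mode round-trips.

    Produces a thalamus mask (V nonzero voxels at each series'
    ``voxel_coords``), a toy cortical parcellation (``rois_per_network``
    ROIs per network, each one voxel here, placed beyond the thalamus
    along x), a ROI->network membership TSV, per-subject 4-D volumes
    whose mask voxels carry ``thal_ts`` and whose ROI voxels carry the
    owning network's course, and the cohort TSV.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    first = next(iter(timeseries.values()))
    coords = first.voxel_coords
    v, k = first.n_voxels, first.n_networks
    nx, ny, nz = grid_shape
    if np.any(coords.max(axis=0) >= [nx, ny, nz]) or np.any(coords < 0):
        raise ValueError(f"grid {grid_shape} too small for {v} thalamus voxels")

    affine = np.eye(4)
    mask = np.zeros(grid_shape, dtype=np.int16)
    mask[tuple(coords.T)] = 1

    # ROI voxels on the plane x = thal_extent + 2, one grid cell per ROI
    n_rois = k * rois_per_network
    roi_x = int(coords[:, 0].max()) + 2
    if roi_x >= nx or n_rois > ny * nz:
        raise ValueError(f"grid {grid_shape} too small to host {n_rois} cortical ROIs")
    roi_cells = [(roi_x, i // nz, i % nz) for i in range(n_rois)]
    parc = np.zeros(grid_shape, dtype=np.int16)
    membership = []
    for roi_id, cell in enumerate(roi_cells, start=1):
        parc[cell] = roi_id
        membership.append({"roi_id": roi_id,
                           "network_name": f"net_{(roi_id - 1) % k + 1}"})
    membership_df = pd.DataFrame(membership).sort_values("roi_id")

    paths = {
        "mask": out_dir / "thalamus_mask.nii.gz",
        "parcellation": out_dir / "parcellation.nii.gz",
        "membership": out_dir / "membership.tsv",
        "cohort": out_dir / "cohort.tsv",
    }
    nib.save(nib.Nifti1Image(mask, affine), paths["mask"])
    nib.save(nib.Nifti1Image(parc, affine), paths["parcellation"])
    membership_df.to_csv(paths["membership"], sep="\t", index=False)
    cohort.to_csv(paths["cohort"], sep="\t", index=False)

    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))  # C-order scan
    for sid, sts in timeseries.items():
        vol = np.zeros((*grid_shape, sts.n_frames), dtype=np.float64)
        vol[tuple(coords[order].T)] = sts.thal_ts[:, order].T
        for roi_id, cell in enumerate(roi_cells, start=1):
            vol[cell] = sts.network_ts[:, (roi_id - 1) % k]
        p = out_dir / f"{sid}_bold.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths[sid] = p
    return paths
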