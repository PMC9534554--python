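"""End-to-end orchestration: simulate -> preprocess -> ISFC -> GLM -> report.

Ties the generator, preprocessing, ISFC core and inference together
into one reproducible run.  A single global seed is expanded into
per-stage child streams (see :func:`isfcpipe.synthgen.stream_rng`), all
thresholds live in one serialisable :class:`PipelineConfig`, statistics
are written as TSV so runs can be diffed byte-for-byte, and every
exclusion / censoring / masking decision is logged with a
machine-parsable prefix.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, isfc, prep, synthgen

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    mode: str = "synthetic"              # "synthetic" | "real"
    out_dir: str = "isfc_run"
    seed: int = 0
    # analysis parameters
    bin_width: int = 10
    fdr_q: float = 0.05
    min_cluster: int = 23
    connectivity: int = 6
    band_low: float = 0.01
    band_high: float = 0.08
    tr: float = 2.47
    fd_threshold: float = 0.5
    trans_limit: float = 2.5
    rot_limit_deg: float = 2.5
    trim: int = 5
    mfd_exclusion: "float | None" = None  # drop subjects with mFD above this
    rot_degrees: bool = False            # motion TSVs carry rotations in deg
    age_model: str = "quadratic"         # "quadratic" | "linear"
    fdr_scope: str = "per-network"       # "per-network" | "global"
    symmetrize: bool = False
    split_half: bool = True
    # synthetic-mode cohort/coupling parameters
    n_subjects: int = 140
    n_networks: int = 17
    n_voxels: int = 620
    n_frames: int = 193                  # retained frames (after trimming)
    intrinsic_loading: float = 0.1
    network_coupling: float = 0.25
    null_coupling: float = 0.4
    coupling_young: float = 0.6
    coupling_old: float = 0.2
    effect_voxels_per_network: int = 30
    n_effect_networks: int = 2
    # real-mode inputs
    cohort_path: "str | None" = None
    timeseries_dir: "str | None" = None
    mask_path: "str | None" = None
    parcellation_path: "str | None" = None
    membership_path: "str | None" = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.age_model not in ("quadratic", "linear"):
            raise ValueError("age_model must be 'quadratic' or 'linear'")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.fd_threshold <= 0 or self.min_cluster < 1:
            raise ValueError("fd_threshold must be > 0 and min_cluster >= 1")

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# synthetic-mode data generation


def default_coupling_model(cfg: PipelineConfig) -> synthgen.CouplingModel:
    """The run's ground truth: age-declining coupling on designated voxels.

    The first ``effect_voxels_per_network`` voxels of the first
    ``n_effect_networks`` networks' blocks decline linearly from
    ``coupling_young`` to ``coupling_old`` across the age range; all
    other voxels keep a constant ``null_coupling``.
    """
    assignment = synthgen.block_assignment(cfg.n_voxels, cfg.n_networks)
    effect = []
    for net in range(min(cfg.n_effect_networks, cfg.n_networks)):
        members = np.flatnonzero(assignment == net)
        effect.extend(members[: cfg.effect_voxels_per_network])
    return synthgen.age_effect_model(
        cfg.n_networks, cfg.n_voxels, np.array(effect, dtype=int),
        network_coupling=cfg.network_coupling,
        null_coupling=cfg.null_coupling,
        coupling_young=cfg.coupling_young,
        coupling_old=cfg.coupling_old,
    )


def cohort_config(cfg: PipelineConfig, n_frames: "int | None" = None) -> synthgen.CohortConfig:
    return synthgen.CohortConfig(
        n_subjects=cfg.n_subjects,
        n_networks=cfg.n_networks,
        n_voxels=cfg.n_voxels,
        n_frames=cfg.n_frames if n_frames is None else n_frames,
        tr=cfg.tr,
        intrinsic_loading=cfg.intrinsic_loading,
        seed=cfg.seed,
    )


def simulate_raw(cfg: PipelineConfig):
    """Generate cohort, raw (untrimmed) series, motion and nuisance channels.

    Raw series carry ``trim`` extra leading frames so that, after the
    preprocessing chain trims them, the retained length is
    ``cfg.n_frames``.
    """
    t_total = cfg.n_frames + cfg.trim
    gen_cfg = cohort_config(cfg, n_frames=t_total)
    cohort = synthgen.generate_cohort(gen_cfg)
    model = default_coupling_model(cfg)
    stimulus = synthgen.generate_stimulus(gen_cfg)
    series, motions, nuisance = {}, {}, {}
    for idx, row in cohort.iterrows():
        sid = row["subject_id"]
        series[sid] = synthgen.generate_subject_data(
            int(idx), float(row["age"]), stimulus, model, gen_cfg, subject_id=sid)
        motions[sid] = synthgen.generate_motion_trace(int(idx), gen_cfg)
        nuisance[sid] = synthgen.generate_wm_csf(int(idx), gen_cfg)
    return cohort, series, motions, nuisance, model


def preprocess_cohort(cfg: PipelineConfig, cohort, series, motions, nuisance):
    """Motion exclusion + the full temporal preprocessing chain.

    Returns the surviving cohort with an ``mfd`` column appended and the
    preprocessed series keyed by subject id.  Excluded subjects are
    logged with the EXCLUDE prefix.
    """
    kept_rows, processed = [], {}
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        if prep.subject_motion_exclusion(motions[sid], cfg.trans_limit,
                                         cfg.rot_limit_deg):
            logger.info("EXCLUDE subject=%s reason=motion", sid)
            continue
        sts, mfd = prep.preprocess_subject(
            series[sid], motions[sid],
            extra_nuisance=None if nuisance is None else nuisance.get(sid),
            trim=cfg.trim, fd_threshold=cfg.fd_threshold,
            band=(cfg.band_low, cfg.band_high),
        )
        if cfg.mfd_exclusion is not None and mfd > cfg.mfd_exclusion:
            logger.info("EXCLUDE subject=%s reason=mfd %.3f > %.3f",
                        sid, mfd, cfg.mfd_exclusion)
            continue
        processed[sid] = sts
        r = row.copy()
        r["mfd"] = mfd
        kept_rows.append(r)
    if len(kept_rows) < 2:
        raise ValueError("fewer than 2 subjects survive motion exclusion")
    out = pd.DataFrame(kept_rows).reset_index(drop=True)
    return out, processed


def attach_mfd(cohort: pd.DataFrame, motions: "dict") -> pd.DataFrame:
    """Append an mFD column computed from raw motion traces (no censoring)."""
    out = cohort.copy()
    out["mfd"] = [
        prep.mean_fd(prep.framewise_displacement(motions[sid]))
        for sid in out["subject_id"]
    ]
    return out


# ---------------------------------------------------------------------------
# analysis core (shared by full runs, split-half and acceptance checks)


@dataclass
class AnalysisResult:
    groups: isfc.AgeGroupSpec
    matrices: "list[isfc.ISFCMatrix]"
    mask: np.ndarray                     # (K, V) analysis mask
    t_values: np.ndarray                 # (K, V) one-sample t
    edges: "list[tuple[int, int]]"       # masked (network, voxel) edges
    z_matrix: np.ndarray                 # (subjects, edges), cohort row order
    subject_order: "list[str]"
    age_table: pd.DataFrame
    behavior_table: "pd.DataFrame | None"
    clusters: "list[inference.Cluster]"


def isfc_stage(cfg: PipelineConfig, cohort: pd.DataFrame, series_by_id: "dict"):
    """Age binning -> leave-one-out ISFC -> one-sample-t/FDR analysis mask."""
    groups = isfc.bin_by_age(cohort, width=cfg.bin_width)
    logger.info("GROUPS n=%d sizes=%s", len(groups.groups),
                [g.n for g in groups.groups])
    matrices = isfc.cohort_isfc(groups, series_by_id, symmetrize=cfg.symmetrize)
    mask, t_values = isfc.significance_mask(matrices, q=cfg.fdr_q)
    logger.info("MASK edges=%d of %d", int(mask.sum()), mask.size)
    return groups, matrices, mask, t_values


def glm_stage(cfg: PipelineConfig, cohort: pd.DataFrame,
              matrices: "list", mask: np.ndarray, voxel_coords: np.ndarray):
    """Edge-wise GLMs on masked edges + FDR + cluster-extent filtering."""
    by_id = {m.subject_id: m for m in matrices}
    subject_order = list(cohort["subject_id"])
    edges = [tuple(e) for e in np.argwhere(mask)]
    if not edges:
        raise ValueError("analysis mask is empty; no edges to model")
    rows = np.stack([by_id[sid].values for sid in subject_order])
    z_matrix = rows[:, mask]             # (S, E) in argwhere order

    design_age = inference.build_design_age(
        cohort, quadratic=cfg.age_model == "quadratic")
    age_table = inference.fit_edge_glm(z_matrix, design_age, edges)
    age_table = inference.apply_fdr(age_table, q=cfg.fdr_q, scope=cfg.fdr_scope)

    behavior_table = None
    has_fi = cohort["fluid_intelligence"].notna()
    if (~has_fi).any():
        logger.info("EXCLUDE behavior-model subjects=%d reason=missing-score",
                    int((~has_fi).sum()))
    sub = cohort[has_fi]
    if len(sub) > len(inference.BEHAVIOR_COLUMNS) + 12:
        design_beh = inference.build_design_behavior(sub)
        z_beh = z_matrix[has_fi.to_numpy()]
        behavior_table = inference.fit_edge_glm(z_beh, design_beh, edges)
        behavior_table = inference.apply_fdr(behavior_table, q=cfg.fdr_q,
                                             scope=cfg.fdr_scope)

    clusters = inference.cluster_maps(age_table, voxel_coords,
                                      min_size=cfg.min_cluster,
                                      connectivity=cfg.connectivity)
    if behavior_table is not None:
        clusters += inference.cluster_maps(behavior_table, voxel_coords,
                                           min_size=cfg.min_cluster,
                                           connectivity=cfg.connectivity)
    age_table = inference.annotate_clusters(age_table, clusters)
    if behavior_table is not None:
        behavior_table = inference.annotate_clusters(behavior_table, clusters)

    def finalize(table, model_name):
        out = table.copy()
        out.insert(0, "model", model_name)
        grid = voxel_coords[out["voxel"].to_numpy(int)]
        out["i"], out["j"], out["k"] = grid[:, 0], grid[:, 1], grid[:, 2]
        return out

    age_table = finalize(age_table, "age")
    if behavior_table is not None:
        behavior_table = finalize(behavior_table, "behavior")
    return edges, z_matrix, subject_order, age_table, behavior_table, clusters


def analyze_cohort(cfg: PipelineConfig, cohort: pd.DataFrame,
                   series_by_id: "dict") -> AnalysisResult:
    """Age binning -> leave-one-out ISFC -> t/FDR mask -> GLMs -> clusters."""
    if "mfd" not in cohort.columns:
        raise ValueError("cohort lacks an 'mfd' column; run preprocessing "
                         "or attach_mfd first")
    groups, matrices, mask, t_values = isfc_stage(cfg, cohort, series_by_id)
    coords = next(iter(series_by_id.values())).voxel_coords
    (edges, z_matrix, subject_order, age_table,
     behavior_table, clusters) = glm_stage(cfg, cohort, matrices, mask, coords)
    return AnalysisResult(groups=groups, matrices=matrices, mask=mask,
                          t_values=t_values, edges=edges, z_matrix=z_matrix,
                          subject_order=subject_order, age_table=age_table,
                          behavior_table=behavior_table, clusters=clusters)


def split_half_validation(cfg: PipelineConfig, cohort: pd.DataFrame,
                          series_by_id: "dict",
                          full: "AnalysisResult | None" = None,
                          seed: "int | None" = None) -> dict:
    """Re-run the analysis on a random half and compare coefficient signs.

    Selects floor(n/2) subjects (seeded), reruns binning/ISFC/GLM on the
    half, and reports, per coefficient of interest, the fraction of
    full-cohort rejected edges whose half-cohort estimate has the same
    sign.
    """
    n = len(cohort)
    if n < 40:
        raise ValueError("split-half validation needs at least 40 subjects")
    if full is None:
        full = analyze_cohort(cfg, cohort, series_by_id)
    rng = synthgen.stream_rng(cfg.seed if seed is None else seed, "misc", 999)
    half_idx = np.sort(rng.choice(n, size=n // 2, replace=False))
    half = cohort.iloc[half_idx].reset_index(drop=True)
    try:
        half_res = analyze_cohort(cfg, half, series_by_id)
    except ValueError as err:
        raise ValueError(
            f"split-half failed ({err}); try another seed or wider bins"
        ) from err

    report: dict = {"n_half": int(len(half)),
                    "half_subjects": list(half["subject_id"]),
                    "concordance": {}}
    pairs = [("age", full.age_table, half_res.age_table)]
    if full.behavior_table is not None and half_res.behavior_table is not None:
        pairs.append(("behavior", full.behavior_table, half_res.behavior_table))
    for model, f_tab, h_tab in pairs:
        for coef in sorted(f_tab["coefficient"].unique()):
            frac, n_edges = inference.sign_concordance(f_tab, h_tab, coef)
            report["concordance"][f"{model}:{coef}"] = {
                "sign_concordance": None if np.isnan(frac) else float(frac),
                "n_edges": int(n_edges),
            }
    return report


# ---------------------------------------------------------------------------
# real-data input mode


def read_inputs(cfg: PipelineConfig):
    """Load cohort, per-subject series and motion for real-data mode.

    The cohort TSV needs columns subject_id, age, sex, education_years,
    brain_volume, fluid_intelligence, motion_path and either a
    timeseries_path column (TSV with net_1..net_K then vox_1..vox_V
    columns) or a bold_path column naming a 4-D NIfTI, in which case
    mask/parcellation/membership NIfTI+TSV paths must be configured.
    Voxel order is the C-order scan of nonzero mask voxels.
    """
    if cfg.cohort_path is None:
        raise ValueError("real mode requires cohort_path")
    root = Path(cfg.cohort_path).parent
    cohort = pd.read_csv(cfg.cohort_path, sep="\t")
    required = {"subject_id", "age", "sex", "education_years", "brain_volume",
                "fluid_intelligence", "motion_path"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    mask_coords = parc_labels = membership = parc_coords = None
    if "bold_path" in cohort.columns:
        import nibabel as nib

        if not (cfg.mask_path and cfg.parcellation_path and cfg.membership_path):
            raise ValueError("NIfTI mode needs mask, parcellation and "
                             "membership paths")
        mask_img = np.asarray(nib.load(cfg.mask_path).dataobj)
        parc_img = np.asarray(nib.load(cfg.parcellation_path).dataobj)
        mask_coords = np.argwhere(mask_img > 0)
        parc_coords = np.argwhere(parc_img > 0)
        parc_labels = parc_img[tuple(parc_coords.T)].astype(int)
        membership = pd.read_csv(cfg.membership_path, sep="\t")

    series, motions = {}, {}
    nuisance: "dict | None" = {} if "nuisance_path" in cohort.columns else None
    t_ref = None
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        motion = pd.read_csv(root / row["motion_path"], sep="\t").to_numpy(float)
        if cfg.rot_degrees:
            motion[:, 3:] = np.radians(motion[:, 3:])
        if nuisance is not None:
            nuisance[sid] = pd.read_csv(root / row["nuisance_path"],
                                        sep="\t").to_numpy(float)
        if "bold_path" in cohort.columns:
            import nibabel as nib

            vol = np.asarray(nib.load(root / row["bold_path"]).dataobj)
            thal = vol[tuple(mask_coords.T)].T            # (T, V)
            cortex = vol[tuple(parc_coords.T)].T          # (T, N)
            net_ts, _ = prep.extract_network_timecourses(cortex, parc_labels,
                                                         membership)
            sts = prep.SubjectTimeSeries(subject_id=sid, network_ts=net_ts,
                                         thal_ts=thal,
                                         voxel_coords=mask_coords, tr=cfg.tr)
        else:
            table = pd.read_csv(root / row["timeseries_path"], sep="\t")
            net_cols = [c for c in table.columns if c.startswith("net_")]
            vox_cols = [c for c in table.columns if c.startswith("vox_")]
            if not net_cols or not vox_cols:
                raise ValueError(
                    f"{row['timeseries_path']}: expected net_*/vox_* columns")
            sts = prep.SubjectTimeSeries(subject_id=sid,
                                         network_ts=table[net_cols].to_numpy(),
                                         thal_ts=table[vox_cols].to_numpy(),
                                         tr=cfg.tr)
        if t_ref is None:
            t_ref = sts.n_frames
        elif sts.n_frames != t_ref:
            raise ValueError(f"subject {sid}: frame count {sts.n_frames} "
                             f"differs from {t_ref}")
        if motion.shape[0] != sts.n_frames:
            raise ValueError(f"subject {sid}: motion rows do not match frames")
        series[sid], motions[sid] = sts, motion
    return cohort, series, motions, nuisance


# ---------------------------------------------------------------------------
# run orchestration and output writing


def write_raw_inputs(out_dir: "str | Path", cohort: pd.DataFrame,
                     series: "dict", motions: "dict",
                     nuisance: "dict | None" = None) -> Path:
    """Write raw inputs as the TSV set that real-data mode consumes.

    Per-subject time-series TSVs (columns net_1..net_K then
    vox_1..vox_V), motion TSVs (6 columns, mm then radians), optional
    nuisance-channel TSVs (WM/CSF means), and a cohort TSV with
    motion_path/timeseries_path (and nuisance_path) columns.
    """
    out = Path(out_dir)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(exist_ok=True)
    if nuisance:
        (out / "nuisance").mkdir(exist_ok=True)
    paths: "dict[str, list]" = {"motion_path": [], "timeseries_path": []}
    for sid in cohort["subject_id"]:
        sts = series[sid]
        ts = pd.DataFrame({
            **{f"net_{k + 1}": sts.network_ts[:, k]
               for k in range(sts.n_networks)},
            **{f"vox_{v + 1}": sts.thal_ts[:, v] for v in range(sts.n_voxels)},
        })
        ts.to_csv(out / "timeseries" / f"{sid}.tsv", sep="\t", index=False)
        pd.DataFrame(motions[sid], columns=["trans_x", "trans_y", "trans_z",
                                            "rot_pitch", "rot_roll", "rot_yaw"]
                     ).to_csv(out / "motion" / f"{sid}.tsv", sep="\t",
                              index=False)
        paths["motion_path"].append(f"motion/{sid}.tsv")
        paths["timeseries_path"].append(f"timeseries/{sid}.tsv")
        if nuisance:
            cols = [f"nuis_{j + 1}" for j in range(nuisance[sid].shape[1])]
            pd.DataFrame(nuisance[sid], columns=cols).to_csv(
                out / "nuisance" / f"{sid}.tsv", sep="\t", index=False)
            paths.setdefault("nuisance_path", []).append(
                f"nuisance/{sid}.tsv")
    cohort.assign(**paths).to_csv(out / "cohort.tsv", sep="\t", index=False)
    return out


def write_processed(out_dir: "str | Path", cohort: pd.DataFrame,
                    series: "dict") -> Path:
    """Persist preprocessed series (with frame masks) for later stages."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    first = next(iter(series.values()))
    pd.DataFrame(first.voxel_coords, columns=["i", "j", "k"]).to_csv(
        out / "voxel_coords.tsv", sep="\t", index=False)
    for sid in cohort["subject_id"]:
        sts = series[sid]
        ts = pd.DataFrame({
            "retained": sts.frame_mask.astype(int),
            **{f"net_{k + 1}": sts.network_ts[:, k]
               for k in range(sts.n_networks)},
            **{f"vox_{v + 1}": sts.thal_ts[:, v] for v in range(sts.n_voxels)},
        })
        ts.to_csv(out / "timeseries" / f"{sid}.tsv", sep="\t", index=False,
                  float_format="%.17g")
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False,
                  float_format="%.17g")
    return out


def read_processed(in_dir: "str | Path", tr: float = 2.47):
    """Load what :func:`write_processed` wrote."""
    root = Path(in_dir)
    cohort = pd.read_csv(root / "cohort.tsv", sep="\t")
    coords = pd.read_csv(root / "voxel_coords.tsv", sep="\t").to_numpy(int)
    series = {}
    for sid in cohort["subject_id"]:
        table = pd.read_csv(root / "timeseries" / f"{sid}.tsv", sep="\t")
        net_cols = [c for c in table.columns if c.startswith("net_")]
        vox_cols = [c for c in table.columns if c.startswith("vox_")]
        series[sid] = prep.SubjectTimeSeries(
            subject_id=sid,
            network_ts=table[net_cols].to_numpy(),
            thal_ts=table[vox_cols].to_numpy(),
            frame_mask=table["retained"].to_numpy(bool),
            voxel_coords=coords, tr=tr)
    return cohort, series


def write_isfc_outputs(out_dir: "str | Path", matrices: "list",
                       mask: np.ndarray, t_values: np.ndarray) -> Path:
    out = Path(out_dir)
    isfc_dir = out / "isfc"
    isfc_dir.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        _matrix_tsv(m.values, isfc_dir / f"{m.subject_id}.tsv")
        (isfc_dir / f"{m.subject_id}.json").write_text(json.dumps({
            "subject_id": m.subject_id, "group_id": int(m.group_id),
            "n_pairs": int(m.n_pairs), "scale": m.scale}, sort_keys=True))
    _matrix_tsv(mask.astype(int), out / "mask.tsv")
    _matrix_tsv(t_values, out / "mask_t.tsv")
    return out


def read_isfc_outputs(in_dir: "str | Path"):
    """Load subject ISFC matrices and the analysis mask back from a run dir."""
    root = Path(in_dir)
    matrices = []
    for meta_path in sorted((root / "isfc").glob("*.json")):
        meta = json.loads(meta_path.read_text())
        values = pd.read_csv(meta_path.with_suffix(".tsv"), sep="\t",
                             index_col="network").to_numpy(float)
        matrices.append(isfc.ISFCMatrix(subject_id=meta["subject_id"],
                                        group_id=meta["group_id"],
                                        values=values,
                                        n_pairs=meta["n_pairs"],
                                        scale=meta["scale"]))
    mask = pd.read_csv(root / "mask.tsv", sep="\t",
                       index_col="network").to_numpy(int).astype(bool)
    return matrices, mask


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _matrix_tsv(values: np.ndarray, path: Path) -> None:
    k, v = values.shape
    df = pd.DataFrame(values, index=[f"net_{i + 1}" for i in range(k)],
                      columns=[f"vox_{j + 1}" for j in range(v)])
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="network")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute a full run and write all artefacts into the run directory.

    Identical config + seed gives byte-identical statistics TSVs.
    Outputs: config snapshot, cohort table, per-subject ISFC matrices
    (+ sidecar JSON), analysis mask and t-map, edge-stat tables for both
    models, cluster inventory, split-half report, log, and a manifest
    with SHA-256 checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root_logger = logging.getLogger("isfcpipe")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        cfg.to_yaml(out / "config.yaml")
        if cfg.mode == "synthetic":
            cohort, series, motions, nuisance, model = simulate_raw(cfg)
            (out / "ground_truth.json").write_text(model.to_json())
        else:
            cohort, series, motions, nuisance = read_inputs(cfg)
        cohort, processed = preprocess_cohort(cfg, cohort, series, motions,
                                              nuisance)
        result = analyze_cohort(cfg, cohort, processed)

        _write_tsv(cohort, out / "cohort.tsv")
        write_isfc_outputs(out, result.matrices, result.mask, result.t_values)
        _write_tsv(result.age_table, out / "stats_age.tsv")
        if result.behavior_table is not None:
            _write_tsv(result.behavior_table, out / "stats_behavior.tsv")
        (out / "clusters.json").write_text(json.dumps(
            [dataclasses.asdict(c) for c in result.clusters], sort_keys=True))
        coords = next(iter(processed.values())).voxel_coords
        inference.export_tmaps_nifti(result.age_table, coords, out / "tmaps")
        if result.behavior_table is not None:
            inference.export_tmaps_nifti(result.behavior_table, coords,
                                         out / "tmaps")
        report = {"maps": inference.map_summary(result.age_table)}
        if result.behavior_table is not None:
            report["maps"] += inference.map_summary(result.behavior_table)
        report["clusters"] = [{"network": c.network,
                               "coefficient": c.coefficient,
                               "sign": c.sign, "size": c.size}
                              for c in result.clusters]

        if cfg.split_half and len(cohort) >= 40:
            sh = split_half_validation(cfg, cohort, processed, full=result)
            (out / "splithalf.json").write_text(
                json.dumps(sh, sort_keys=True, indent=1))
            report["splithalf_concordance"] = sh["concordance"]
        else:
            logger.info("SPLITHALF skipped (disabled or n < 40)")
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))

        manifest = {
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "config_sha256": hashlib.sha256(
                yaml.safe_dump(dataclasses.asdict(cfg),
                               sort_keys=True).encode()).hexdigest(),
            "outputs": {},
        }
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest["outputs"][str(p.relative_to(out))] = hashlib.sha256(
                    p.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        return out
    finally:
        root_logger.removeHandler(handler)
        handler.close()
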