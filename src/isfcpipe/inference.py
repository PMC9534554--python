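"""Edge-wise GLMs for age and behaviour, FDR, and cluster-extent filtering.

Each edge's Fisher-z ISFC value across subjects is regressed on either

    age model:       z = b0 + b1*age_c + b2*age_c^2 + b3*sex + b4*education
                         + b5*mFD + b6*volume
    behaviour model: z = b0 + b1*behavior + b2*sex + b3*education
                         + b5*mFD + b6*volume

(age centred at the sample mean before squaring, which decorrelates the
linear and quadratic terms).  Coefficients of interest — the age terms
and the behaviour slope — are tested with T statistics, corrected with
Benjamini-Hochberg FDR, and the surviving voxels of each network map
are filtered by cluster extent (default: face-connected components of
at least 23 voxels, positive and negative effects clustered
separately).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .isfc import bh_qvalues

logger = logging.getLogger(__name__)

AGE_COLUMNS = ["intercept", "age_c", "age_c2", "sex", "education", "mfd", "volume"]
BEHAVIOR_COLUMNS = ["intercept", "behavior", "sex", "education", "mfd", "volume"]
AGE_COEFS_OF_INTEREST = ("age_c", "age_c2")
BEHAVIOR_COEFS_OF_INTEREST = ("behavior",)
DEFAULT_MIN_CLUSTER = 23
CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class DesignMatrix:
    """Named, full-rank design matrix plus its centering record."""

    x: np.ndarray
    columns: tuple
    model: str                   # "age" or "behavior"
    age_center: "float | None" = None
    subject_ids: tuple = ()

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]


def _check_rank(x: np.ndarray, columns: "list[str]") -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        constant = [c for j, c in enumerate(columns)
                    if j > 0 and np.std(x[:, j]) == 0]
        detail = f" (constant columns: {constant})" if constant else ""
        raise ValueError(f"design matrix is rank deficient{detail}")


def _covariates(cohort: pd.DataFrame) -> np.ndarray:
    required = ["sex", "education_years", "mfd", "brain_volume"]
    missing = [c for c in required if c not in cohort or cohort[c].isna().any()]
    if missing:
        raise ValueError(f"missing covariate values in columns: {missing}")
    return np.column_stack([
        cohort["sex"].to_numpy(float),
        cohort["education_years"].to_numpy(float),
        cohort["mfd"].to_numpy(float),
        cohort["brain_volume"].to_numpy(float),
    ])


def build_design_age(cohort: pd.DataFrame, quadratic: bool = True) -> DesignMatrix:
    """Design for the lifespan model: [1, age_c, age_c^2, sex, education, mFD, volume].

    Age is centred at the sample mean before squaring (recorded in
    ``age_center``); with ``quadratic=False`` the squared term is
    omitted for a linear-only age model.
    """
    age = cohort["age"].to_numpy(float)
    if np.isnan(age).any():
        raise ValueError("missing ages")
    center = float(age.mean())
    age_c = age - center
    age_cols = [age_c, age_c ** 2] if quadratic else [age_c]
    names = AGE_COLUMNS if quadratic else [c for c in AGE_COLUMNS if c != "age_c2"]
    x = np.column_stack([np.ones(len(age)), *age_cols, _covariates(cohort)])
    if x.shape[0] <= x.shape[1] + 2:
        raise ValueError("too few subjects for the age design")
    _check_rank(x, names)
    return DesignMatrix(x=x, columns=tuple(names), model="age",
                        age_center=center,
                        subject_ids=tuple(cohort["subject_id"]))


def build_design_behavior(cohort: pd.DataFrame) -> DesignMatrix:
    """Design for the behaviour model: [1, behavior, sex, education, mFD, volume].

    Age is deliberately absent: age and fluid intelligence are strongly
    collinear, so behaviour gets its own model with the same covariates.
    """
    fi = cohort["fluid_intelligence"].to_numpy(float)
    if np.isnan(fi).any():
        raise ValueError("missing behaviour scores; drop those subjects first")
    x = np.column_stack([np.ones(len(fi)), fi, _covariates(cohort)])
    if x.shape[0] <= x.shape[1] + 2:
        raise ValueError("too few subjects for the behaviour design")
    _check_rank(x, BEHAVIOR_COLUMNS)
    return DesignMatrix(x=x, columns=tuple(BEHAVIOR_COLUMNS), model="behavior",
                        subject_ids=tuple(cohort["subject_id"]))


def _ols_stats(x: np.ndarray, y: np.ndarray) -> "tuple[np.ndarray, np.ndarray, int]":
    """Vectorised OLS of every column of y on x: (beta, se, df)."""
    n, p = x.shape
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                       # (p, E)
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df         # (E,)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return beta, se, df


def fit_edge_glm(
    z_values: np.ndarray,
    design: DesignMatrix,
    edges: "list[tuple[int, int]]",
    coefs_of_interest: "tuple[str, ...] | None" = None,
) -> pd.DataFrame:
    """Edge-wise OLS with T statistics for the coefficients of interest.

    ``z_values`` is (subjects x edges), rows aligned to the design;
    ``edges`` gives each column's (network, voxel) identity.  Subjects
    with a non-finite value at an edge are dropped pairwise for that
    edge (logged).  Returns a long-format table: network, voxel,
    coefficient, estimate, se, t, p.
    """
    z = np.asarray(z_values, dtype=float)
    if z.shape[0] != design.n:
        raise ValueError("z rows must align with design rows")
    if z.shape[1] != len(edges):
        raise ValueError("one edge id per z column is required")
    if coefs_of_interest is None:
        wanted = (AGE_COEFS_OF_INTEREST if design.model == "age"
                  else BEHAVIOR_COEFS_OF_INTEREST)
        coefs_of_interest = tuple(c for c in wanted if c in design.columns)
    bad = [c for c in coefs_of_interest if c not in design.columns]
    if bad:
        raise ValueError(f"unknown coefficients: {bad}")
    min_df = 10
    x = design.x
    finite = np.isfinite(z)
    complete = finite.all(axis=0)
    n_partial = int((~complete).sum())
    if n_partial:
        logger.info("GLM pairwise-dropping subjects at %d edges", n_partial)

    p_cols = {c: j for j, c in enumerate(design.columns)}
    rows = []

    def emit(edge_idx: "np.ndarray", beta, se, df):
        tt = beta / se
        pp = 2.0 * stats.t.sf(np.abs(tt), df=df)
        for c in coefs_of_interest:
            j = p_cols[c]
            for m, e in enumerate(edge_idx):
                k, v = edges[e]
                rows.append((k, v, c, beta[j, m], se[j, m], tt[j, m], pp[j, m], df))

    complete_idx = np.flatnonzero(complete)
    if complete_idx.size:
        if x.shape[0] - x.shape[1] < min_df:
            raise ValueError("residual degrees of freedom below 10")
        beta, se, df = _ols_stats(x, z[:, complete_idx])
        emit(complete_idx, beta, se, df)
    for e in np.flatnonzero(~complete):
        keep = finite[:, e]
        if keep.sum() - x.shape[1] < min_df:
            raise ValueError(
                f"residual degrees of freedom below 10 at edge {edges[e]}"
            )
        beta, se, df = _ols_stats(x[keep], z[keep, e][:, None])
        emit(np.array([e]), beta, se, df)

    table = pd.DataFrame(rows, columns=["network", "voxel", "coefficient",
                                        "estimate", "se", "t", "p", "df"])
    return table.sort_values(["coefficient", "network", "voxel"],
                             ignore_index=True)


def bh_fdr(p: np.ndarray, q: float = 0.05) -> "tuple[np.ndarray, np.ndarray]":
    """Benjamini-Hochberg step-up over one family of p-values."""
    return bh_qvalues(p, q)


def apply_fdr(
    table: pd.DataFrame,
    q: float = 0.05,
    scope: str = "per-network",
) -> pd.DataFrame:
    """Attach BH q-values and rejection flags to an edge-stat table.

    ``scope='per-network'`` (default) corrects each (network,
    coefficient) map as its own family — each network's thalamic map
    gets its own corrected threshold.  ``scope='global'`` pools all
    edges of a coefficient into one family.
    """
    if scope not in ("per-network", "global"):
        raise ValueError("scope must be 'per-network' or 'global'")
    out = table.copy()
    out["q"] = np.nan
    out["reject"] = False
    keys = (["coefficient", "network"] if scope == "per-network"
            else ["coefficient"])
    for _, idx in out.groupby(keys).groups.items():
        qv, rej = bh_qvalues(out.loc[idx, "p"].to_numpy(), q)
        out.loc[idx, "q"] = qv
        out.loc[idx, "reject"] = rej
    out["sign"] = np.sign(out["estimate"]).astype(int)
    return out


@dataclass(frozen=True)
class Cluster:
    network: int
    coefficient: str
    sign: int
    size: int
    voxels: tuple              # voxel indices (into the V axis)


def cluster_filter(
    reject_voxels: np.ndarray,
    voxel_coords: np.ndarray,
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 6,
) -> "list[tuple[int, np.ndarray]]":
    """Connected components of rejected voxels, dropping small ones.

    ``reject_voxels`` is a boolean vector over the V thalamic voxels;
    components are found on the integer grid via the chosen adjacency
    (6 = faces, 18 = +edges, 26 = +corners) and those smaller than
    ``min_size`` are removed.  Survivors are returned as (size, voxel
    index array) ordered by their minimum coordinate, lexicographic.
    """
    if connectivity not in CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    reject_voxels = np.asarray(reject_voxels, dtype=bool)
    coords = np.asarray(voxel_coords, dtype=int)
    if coords.shape != (reject_voxels.shape[0], 3):
        raise ValueError("voxel_coords must be (V, 3)")
    if not reject_voxels.any():
        return []
    offset = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - offset + 1)
    grid = np.zeros(shape, dtype=bool)
    sel = coords[reject_voxels] - offset
    grid[tuple(sel.T)] = True
    structure = ndimage.generate_binary_structure(3, CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(grid, structure=structure)
    comp_of_voxel = np.zeros(reject_voxels.shape[0], dtype=int)
    shifted = coords - offset
    comp_of_voxel[reject_voxels] = labels[tuple(shifted[reject_voxels].T)]
    survivors = []
    for comp in range(1, n_comp + 1):
        members = np.flatnonzero(comp_of_voxel == comp)
        if members.size >= min_size:
            key = tuple(coords[members].min(axis=0)) + tuple(
                sorted(map(tuple, coords[members]))[0])
            survivors.append((key, members))
    survivors.sort(key=lambda t: t[0])
    return [(m.size, m) for _, m in survivors]


def cluster_maps(
    table: pd.DataFrame,
    voxel_coords: np.ndarray,
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 6,
) -> "list[Cluster]":
    """Cluster-extent filter per (network, coefficient, sign).

    Positive and negative effects are clustered separately, mirroring
    the warm/cool display convention of thalamic T-maps.
    """
    n_voxels = voxel_coords.shape[0]
    clusters = []
    rejected = table[table["reject"]]
    for (network, coefficient, sign), sub in rejected.groupby(
            ["network", "coefficient", "sign"]):
        flags = np.zeros(n_voxels, dtype=bool)
        flags[sub["voxel"].to_numpy(int)] = True
        for size, members in cluster_filter(flags, voxel_coords,
                                            min_size, connectivity):
            clusters.append(Cluster(network=int(network),
                                    coefficient=str(coefficient),
                                    sign=int(sign), size=int(size),
                                    voxels=tuple(int(v) for v in members)))
    return clusters


def annotate_clusters(table: pd.DataFrame,
                      clusters: "list[Cluster]") -> pd.DataFrame:
    """Add a cluster_id column; rejected edges outside any cluster get -1."""
    out = table.copy()
    out["cluster_id"] = -1
    for cid, cl in enumerate(clusters):
        sel = (out["network"].eq(cl.network)
               & out["coefficient"].eq(cl.coefficient)
               & out["reject"]
               & out["sign"].eq(cl.sign)
               & out["voxel"].isin(cl.voxels))
        out.loc[sel, "cluster_id"] = cid
    return out


def export_tmaps_nifti(table: pd.DataFrame, voxel_coords: np.ndarray,
                       out_dir, grid_shape: "tuple | None" = None) -> "list":
    """Write one thalamic T-map NIfTI per (network, coefficient).

    Each volume is float32 with background 0; voxel (i, j, k) carries
    the edge's T value.  ``grid_shape`` defaults to the bounding box of
    the coordinates.
    """
    import nibabel as nib
    from pathlib import Path

    coords = np.asarray(voxel_coords, dtype=int)
    if grid_shape is None:
        grid_shape = tuple(coords.max(axis=0) + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (network, coefficient), sub in table.groupby(["network",
                                                      "coefficient"]):
        vol = np.zeros(grid_shape, dtype=np.float32)
        sel = coords[sub["voxel"].to_numpy(int)]
        vol[tuple(sel.T)] = sub["t"].to_numpy(np.float32)
        path = out_dir / f"tmap_net-{network}_{coefficient}.nii.gz"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
        written.append(path)
    return written


def map_summary(table: pd.DataFrame) -> "list[dict]":
    """Per-(coefficient, network) rejection counts and corrected thresholds.

    The "corrected threshold equivalent" is the largest uncorrected p
    among that map's rejected edges — the map-specific p < value that
    BH rejection implies.
    """
    rows = []
    for (coefficient, network), sub in table.groupby(["coefficient",
                                                      "network"]):
        rej = sub[sub["reject"]]
        rows.append({
            "coefficient": str(coefficient),
            "network": int(network),
            "n_edges": int(len(sub)),
            "n_rejected": int(len(rej)),
            "n_positive": int((rej["sign"] > 0).sum()),
            "n_negative": int((rej["sign"] < 0).sum()),
            "corrected_p_threshold": (float(rej["p"].max())
                                      if len(rej) else None),
        })
    return rows


def sign_concordance(full: pd.DataFrame, half: pd.DataFrame,
                     coefficient: str) -> "tuple[float, int]":
    """Fraction of full-run rejected edges whose coefficient sign replicates.

    Edges rejected for ``coefficient`` in the full-cohort run are looked
    up in the half-cohort table; concordance is the fraction whose
    estimates agree in sign.  Returns (fraction, n edges compared).
    """
    f = full[(full["coefficient"] == coefficient) & full["reject"]]
    if f.empty:
        return float("nan"), 0
    h = half[half["coefficient"] == coefficient].set_index(["network", "voxel"])
    agree = []
    for _, row in f.iterrows():
        key = (row["network"], row["voxel"])
        if key in h.index:
            agree.append(np.sign(h.loc[key, "estimate"]) == np.sign(row["estimate"]))
    if not agree:
        return float("nan"), 0
    return float(np.mean(agree)), len(agree)
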