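"""EEG-informed GLM of BOLD, group inference, and cluster correction.

Each microstate regressor enters its own subject-level GLM (they are too
collinear to fit jointly) together with nuisance terms: a 3rd-order
polynomial drift block, 12 motion parameters, and optional precomputed
ventricle-PC / local-white-matter columns.  Censored TRs (motion RMS > 0.2
or EEG artifact) are excluded row-wise.  Subject betas go into a group
one-sample t-test; family-wise error over units is controlled by a
sign-flip permutation null on the maximum cluster extent at a voxel-wise
threshold of p < 0.005 and a cluster threshold of p < 0.05.  Significant
clusters are summarised as percentage overlap with a 7-network parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage
import scipy.stats

from .synthetic import BOLDDataset

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "Cluster",
    "ClusterMap",
    "build_design_matrix",
    "fit_subject_glm",
    "group_ttest",
    "permutation_cluster_correction",
    "network_overlap",
]

VOXEL_P = 0.005
CLUSTER_P = 0.05
DEFAULT_N_PERM = 10000
POLY_ORDER = 3


@dataclass
class DesignMatrix:
    """Named design columns (regressor of interest first) as a DataFrame."""

    table: pd.DataFrame
    regressor: str  # name of the column of interest

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class GLMResult:
    """Group-level summary: per-unit mean beta, t statistic, two-sided p."""

    beta: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray
    dof: int
    flagged: np.ndarray  # zero-variance units where t is undefined


@dataclass
class Cluster:
    units: np.ndarray  # unit ids
    size: int
    peak_t: float
    sign: int  # +1 / -1
    pval: float


@dataclass
class ClusterMap:
    clusters: list[Cluster] = field(default_factory=list)
    voxel_p: float = VOXEL_P
    cluster_p: float = CLUSTER_P
    min_extent: int = 0
    null_max_extent: np.ndarray | None = None

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.pval < self.cluster_p]


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

def build_design_matrix(
    regressor: np.ndarray,
    regressor_name: str,
    motion: np.ndarray | None = None,
    poly_order: int = POLY_ORDER,
    extra: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Regressor of interest + orthogonal polynomial drift + nuisance columns.

    Drift uses Legendre polynomials on [-1, 1] (orders 0..poly_order), which
    are mutually orthogonal in the limit and well conditioned.  ``extra``
    carries precomputed nuisance traces (ventricle PCs, local WM average).
    """
    regressor = np.asarray(regressor, dtype=float)
    n = regressor.size
    cols: dict[str, np.ndarray] = {regressor_name: regressor}
    t = np.linspace(-1.0, 1.0, n)
    legendre = np.polynomial.legendre.legvander(t, poly_order)
    for d in range(poly_order + 1):
        cols[f"poly{d}"] = legendre[:, d]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n:
            raise ValueError("motion table not aligned with TRs")
        for i in range(motion.shape[1]):
            cols[f"motion{i:02d}"] = motion[:, i]
    for name, series in (extra or {}).items():
        series = np.asarray(series, dtype=float)
        if series.size != n:
            raise ValueError(f"nuisance column '{name}' not aligned with TRs")
        cols[name] = series
    return DesignMatrix(table=pd.DataFrame(cols), regressor=regressor_name)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose pivot in a rank-revealing QR is (near) zero."""
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] <= tol]


def fit_subject_glm(bold: BOLDDataset, design: DesignMatrix) -> np.ndarray:
    """OLS betas of the regressor of interest, one per unit.

    Censored TRs are dropped from both the data and the design before
    fitting.  A rank-deficient (post-censoring) design raises an error
    naming the collinear columns.
    """
    x = design.values
    if x.shape[0] != bold.n_tr:
        raise ValueError("design rows must equal the number of TRs")
    keep = ~bold.censor
    x = x[keep]
    y = bold.data[:, keep].T  # kept TRs x units
    names = list(design.table.columns)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef[names.index(design.regressor)]


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

def _tmap(betas: np.ndarray) -> np.ndarray:
    """One-sample t per unit; zero-variance units yield +/-inf (or nan at 0)."""
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    se = betas.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / se


def group_ttest(betas: np.ndarray) -> GLMResult:
    """One-sample t-test of subject betas against zero, per unit."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 3:
        raise ValueError("need a subjects x units matrix with >= 3 subjects")
    n = betas.shape[0]
    t = _tmap(betas)
    flagged = ~np.isfinite(t)
    dof = n - 1
    pval = 2.0 * scipy.stats.t.sf(np.abs(np.where(flagged, 0.0, t)), dof)
    pval[flagged] = np.nan
    return GLMResult(beta=betas.mean(axis=0), tstat=t, pval=pval, dof=dof, flagged=flagged)


# ---------------------------------------------------------------------------
# cluster-extent permutation correction
# ---------------------------------------------------------------------------

def _cluster_label_map(mask: np.ndarray, coords: np.ndarray | None) -> np.ndarray:
    """Connected components of a boolean unit mask.

    1-D ROI mode (no coordinates): units are adjacent when their indices are
    consecutive.  Volumetric mode: 26-connectivity on the integer grid.
    Returns per-unit component labels (0 = background).
    """
    if coords is None:
        labels, _ = scipy.ndimage.label(mask.astype(int))
        return labels
    coords = np.asarray(coords, dtype=int)
    offset = coords.min(axis=0)
    shape = coords.max(axis=0) - offset + 1
    vol = np.zeros(shape, dtype=bool)
    ijk = (coords - offset).T
    vol[tuple(ijk)] = mask
    lab_vol, _ = scipy.ndimage.label(vol, structure=np.ones((3,) * coords.shape[1], dtype=int))
    return lab_vol[tuple(ijk)]


def _extents(tvals: np.ndarray, t_crit: float, coords: np.ndarray | None):
    """Suprathreshold clusters for both signs: list of (unit ids, sign)."""
    out = []
    for sign in (1, -1):
        mask = (sign * tvals) > t_crit
        if not mask.any():
            continue
        labels = _cluster_label_map(mask, coords)
        for lab in range(1, labels.max() + 1):
            units = np.flatnonzero(labels == lab)
            if units.size:
                out.append((units, sign))
    return out


def permutation_cluster_correction(
    result: GLMResult,
    betas: np.ndarray,
    unit_coords: np.ndarray | None = None,
    voxel_p: float = VOXEL_P,
    cluster_p: float = CLUSTER_P,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> ClusterMap:
    """Sign-flip permutation null on the maximum cluster extent.

    Under the null of symmetric zero-mean subject effects, each subject's
    beta map can have its sign flipped; the distribution of the maximum
    suprathreshold (|t| > t_crit at ``voxel_p``, two-sided) cluster extent
    over flips gives the family-wise null.  A cluster is significant when
    its permutation p-value (1 + #{null >= extent}) / (1 + n_perm) falls
    below ``cluster_p``.  With few subjects (2^n <= n_perm) all sign
    patterns are enumerated exhaustively.
    """
    betas = np.asarray(betas, dtype=float)
    n_sub, n_units = betas.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    t_crit = scipy.stats.t.ppf(1.0 - voxel_p / 2.0, result.dof)

    if 2**n_sub <= n_perm:
        bits = np.arange(2**n_sub)
        flips = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n_sub)[None, :]) & 1)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))

    null_max = np.zeros(flips.shape[0], dtype=int)
    for q, signs in enumerate(flips):
        t_perm = _tmap(signs[:, None] * betas)
        t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
        cl = _extents(t_perm, t_crit, unit_coords)
        null_max[q] = max((u.size for u, _ in cl), default=0)

    n_null = null_max.size
    tvals = np.where(result.flagged, 0.0, result.tstat)
    clusters = []
    for units, sign in _extents(tvals, t_crit, unit_coords):
        pval = (1.0 + np.sum(null_max >= units.size)) / (1.0 + n_null)
        peak = tvals[units][np.argmax(np.abs(tvals[units]))]
        clusters.append(
            Cluster(units=units, size=units.size, peak_t=float(peak), sign=sign, pval=pval)
        )
    clusters.sort(key=lambda c: -c.size)

    # smallest extent that would reach significance under this null
    sorted_null = np.sort(null_max)
    min_extent = 0
    for m in range(0, int(sorted_null[-1]) + 2):
        p = (1.0 + np.sum(null_max >= m)) / (1.0 + n_null)
        if p < cluster_p:
            min_extent = m
            break
    else:  # degenerate null (e.g. all-equal data): report the largest extent
        min_extent = int(sorted_null[-1])
    return ClusterMap(
        clusters=clusters,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        min_extent=min_extent,
        null_max_extent=null_max,
    )


# ---------------------------------------------------------------------------
# network overlap
# ---------------------------------------------------------------------------

def network_overlap(
    clusters: ClusterMap | list[np.ndarray],
    parcellation: np.ndarray,
    significant_only: bool = True,
) -> pd.Series:
    """Percentage of significant-cluster units falling in each network.

    ``parcellation`` assigns every unit a network id (0 = background, which
    is excluded from the numerator but counted in the cluster total, so
    percentages sum to <= 100).
    """
    parcellation = np.asarray(parcellation, dtype=int)
    if isinstance(clusters, ClusterMap):
        pool = clusters.significant if significant_only else clusters.clusters
        unit_lists = [c.units for c in pool]
    else:
        unit_lists = list(clusters)
    networks = np.unique(parcellation[parcellation > 0])
    if not unit_lists:
        return pd.Series(0.0, index=[f"network_{n}" for n in networks])
    units = np.unique(np.concatenate(unit_lists))
    total = units.size
    vals = {
        f"network_{n}": 100.0 * np.sum(parcellation[units] == n) / total
        for n in networks
    }
    return pd.Series(vals)
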