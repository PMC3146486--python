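"""Mass-univariate voxel-wise inference with cluster-extent FWE correction.

Voxel-wise general-linear-model t maps (two-sample contrasts with
covariates, or age correlations in controls), thresholded at an
uncorrected voxel-level p, with family-wise error control of cluster
extent by Freedman-Lane permutation of the maximum cluster size. The
permutation route replaces parametric random-field correction: it is
exact under exchangeability and fully self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import GridMismatch, RankDeficient
from .io_cohort import VolumeStack
from .masking import MaskVolume

__all__ = [
    "DesignMatrix",
    "StatMap",
    "Cluster",
    "ClusterReport",
    "group_design",
    "glm_t_map",
    "age_correlation_map",
    "label_clusters",
    "cluster_fwe",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # face / face+edge / face+edge+corner


@dataclass
class DesignMatrix:
    """Subjects x predictors matrix with a fixed contrast vector.

    Must be of full column rank; the contrast has one weight per column.
    """

    X: np.ndarray
    contrast: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        n, p = self.X.shape
        if self.contrast.shape != (p,):
            raise ValueError("contrast length must equal the number of columns")
        if not self.names:
            self.names = [f"x{j}" for j in range(p)]
        if np.linalg.matrix_rank(self.X) < p:
            raise RankDeficient("design matrix is rank deficient")
        if n - p <= 0:
            raise RankDeficient(f"df = {n - p} <= 0 (n={n}, p={p})")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - np.linalg.matrix_rank(self.X)


@dataclass
class StatMap:
    """Per-voxel t statistics with residual degrees of freedom."""

    t: np.ndarray  # full-grid map, 0 outside mask
    df: int
    mask: MaskVolume

    @property
    def values(self) -> np.ndarray:
        """t values of masked voxels in fixed grid order."""
        return self.t[self.mask.data]


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    size: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    p_fwe: float


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold_t: float
    voxel_p: float
    n_perm: int
    seed: int
    connectivity: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < alpha]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tsize\tpeak_t\ti\tj\tk\tp_fwe\n")
            for c in self.clusters:
                i, j, k = c.peak_ijk
                fh.write(
                    f"{c.cluster_id}\t{c.size}\t{c.peak_t:.6g}\t{i}\t{j}\t{k}\t{c.p_fwe:.6g}\n"
                )


def group_design(
    group_labels,
    positive,
    covariates: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Two-sample design: [indicator(positive), intercept, covariates...].

    The contrast weights the group indicator, so positive t means the
    ``positive`` group exceeds the other.
    """
    group_labels = np.asarray(group_labels)
    indicator = (group_labels == positive).astype(np.float64)
    cols = [indicator, np.ones(len(group_labels))]
    names = ["group", "intercept"]
    for name, values in (covariates or {}).items():
        cols.append(np.asarray(values, dtype=np.float64))
        names.append(name)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    return DesignMatrix(X, contrast, names)


def _t_stats(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray, df: int) -> np.ndarray:
    """GLM t per column of Y. Zero-variance voxels with zero effect get t=0."""
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    cxxc = float(contrast @ np.linalg.inv(X.T @ X) @ contrast)
    effect = contrast @ beta
    # voxels that the model fits exactly (zero residual variance up to fp
    # noise) carry no evidence either way: define t = 0 there
    scale = np.einsum("ij,ij->j", Y, Y) / Y.shape[0]
    degenerate = sigma2 <= 1e-24 * np.maximum(scale, 1e-300)
    denom = np.sqrt(sigma2 * cxxc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / denom
    t[degenerate | (denom == 0)] = 0.0
    return t


def glm_t_map(
    stack: VolumeStack,
    design: DesignMatrix,
    mask: MaskVolume,
    df_adjust: int = 0,
) -> StatMap:
    """Voxel-wise t for the design's contrast over masked voxels.

    ``df_adjust`` subtracts extra degrees of freedom (e.g. for parameters
    consumed by a detrending pre-regression); default reports nominal df.
    """
    if mask.shape != stack.grid_shape:
        raise GridMismatch("mask grid does not match stack grid")
    if design.n != stack.n_subjects:
        raise GridMismatch(
            f"design rows ({design.n}) != stack subjects ({stack.n_subjects})"
        )
    df = design.df - df_adjust
    if df <= 0:
        raise RankDeficient(f"adjusted df = {df} <= 0")
    Y = stack.to_matrix(mask)
    t = _t_stats(Y, design.X, design.contrast, df)
    t_map = np.zeros(mask.shape)
    t_map[mask.data] = t
    return StatMap(t=t_map, df=df, mask=mask)


def age_correlation_map(
    controls: VolumeStack,
    ages: np.ndarray,
    sex: np.ndarray,
    mask: MaskVolume,
) -> StatMap:
    """Voxel-wise age effect in controls, sex as covariate (t on the age column)."""
    ages = np.asarray(ages, dtype=np.float64)
    X = np.column_stack([ages, np.ones(len(ages)), np.asarray(sex, dtype=np.float64)])
    contrast = np.array([1.0, 0.0, 0.0])
    design = DesignMatrix(X, contrast, ["age", "intercept", "sex"])
    return glm_t_map(controls, design, mask)


def label_clusters(
    suprathreshold: np.ndarray, connectivity: int = 18
) -> tuple[np.ndarray, int]:
    """Connected components of a boolean grid under 6/18/26 connectivity."""
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(suprathreshold, structure=structure)
    return labels, int(n)


def _cluster_sizes(suprathreshold: np.ndarray, connectivity: int) -> np.ndarray:
    labels, n = label_clusters(suprathreshold, connectivity)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    return np.bincount(labels.ravel())[1:]


def cluster_fwe(
    stat_map: StatMap,
    stack: VolumeStack,
    design: DesignMatrix,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
    tail: str = "greater",
) -> ClusterReport:
    """Cluster-extent FWE via the permutation maximum cluster size.

    Voxels are thresholded at the one-tailed ``voxel_p`` quantile of
    Student's t with the map's df (``tail='two-sided'`` thresholds |t|).
    Suprathreshold voxels are labelled into connected components; each
    observed cluster's corrected p is the fraction of permutations (plus
    the identity, the standard +1 convention) whose maximum cluster size
    is at least as large.

    Permutations follow the Freedman-Lane scheme: data are residualised
    against the nuisance columns (zero contrast weight), the residual rows
    are permuted, and the full-model t map recomputed — preserving the
    covariate structure under the null.

    An entirely subthreshold map yields an empty report, not an error.
    """
    if not (0.0 < voxel_p < 1.0):
        raise ValueError("voxel_p must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")

    df = stat_map.df
    if tail == "two-sided":
        t_crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, df))
    else:
        t_crit = float(stats.t.ppf(1.0 - voxel_p, df))

    mask = stat_map.mask

    def exceed(t_values: np.ndarray) -> np.ndarray:
        if tail == "greater":
            return t_values > t_crit
        if tail == "less":
            return t_values < -t_crit
        return np.abs(t_values) > t_crit

    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask.data] = exceed(stat_map.values)
    labels, n_clusters = label_clusters(supra, connectivity)

    if n_clusters == 0:
        return ClusterReport([], t_crit, voxel_p, n_perm, seed, connectivity)

    sizes = np.bincount(labels.ravel())[1:]

    # Freedman-Lane: residualise against nuisance columns, permute rows
    Z = design.X[:, design.contrast == 0]
    Y = stack.to_matrix(mask)
    if Z.shape[1] > 0:
        resid = Y - Z @ (np.linalg.pinv(Z) @ Y)
    else:
        resid = Y
    rng = np.random.default_rng(seed)
    n = design.n

    max_sizes = np.empty(n_perm, dtype=np.int64)
    supra_perm = np.zeros(mask.shape, dtype=bool)
    for r in range(n_perm):
        perm = rng.permutation(n)
        t_perm = _t_stats(resid[perm], design.X, design.contrast, df)
        supra_perm[:] = False
        supra_perm[mask.data] = exceed(t_perm)
        cs = _cluster_sizes(supra_perm, connectivity)
        max_sizes[r] = cs.max() if cs.size else 0

    clusters = []
    for cid in range(1, n_clusters + 1):
        size = int(sizes[cid - 1])
        in_cluster = labels == cid
        t_vals = np.where(in_cluster, stat_map.t, np.nan)
        flat_peak = (
            np.nanargmin(t_vals) if tail == "less" else np.nanargmax(np.abs(t_vals) if tail == "two-sided" else t_vals)
        )
        peak_ijk = tuple(int(v) for v in np.unravel_index(flat_peak, mask.shape))
        peak_t = float(stat_map.t[peak_ijk])
        p_fwe = (1 + int((max_sizes >= size).sum())) / (n_perm + 1)
        clusters.append(Cluster(cid, size, peak_t, peak_ijk, p_fwe))
    clusters.sort(key=lambda c: c.size, reverse=True)
    clusters = [
        Cluster(i + 1, c.size, c.peak_t, c.peak_ijk, c.p_fwe)
        for i, c in enumerate(clusters)
    ]
    return ClusterReport(clusters, t_crit, voxel_p, n_perm, seed, connectivity)
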