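"""LCMV beamforming, neural-activity-index thresholding, and voxel clustering.

Sensor epochs are turned into a small set of source-node time courses in
three steps: (1) a linearly constrained minimum-variance spatial filter per
voxel (unit gain at the voxel, minimum output variance elsewhere); (2) the
neural activity index — beamformer output power normalized by projected
noise power — thresholded to the top 2% of labeled voxels, which corrects
the beamformer's depth bias; (3) DBSCAN over the retained voxel positions
(eps = 1.5 x voxel edge, min 2 voxels) to form clusters, whose mean time
course is the node signal used in connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .core import EpochedSignal


@dataclass
class SourceGrid:
    """Regular voxel grid with lead field and region labels.

    ``leadfield`` is sensors x V for fixed-orientation sources, or
    sensors x V x 3 for free orientation (collapsed to a scalar orientation
    during filter computation).  ``region_labels`` holds one string per
    voxel; an empty string means unlabeled and excluded from thresholding.
    """

    voxel_positions: np.ndarray  # V x 3, mm
    voxel_edge_mm: float
    leadfield: np.ndarray
    region_labels: np.ndarray
    sensor_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxel_positions = np.asarray(self.voxel_positions, dtype=float)
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.leadfield.shape[1] != self.voxel_positions.shape[0]:
            raise ValueError("leadfield column count does not match voxel count")
        if self.region_labels.shape[0] != self.voxel_positions.shape[0]:
            raise ValueError("one region label per voxel required")

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]


@dataclass
class VoxelCluster:
    member_voxels: np.ndarray  # indices into the grid's voxel axis
    label: str
    centroid: np.ndarray
    timecourse: np.ndarray | None = None  # trials x samples

    @property
    def size(self) -> int:
        return len(self.member_voxels)


@dataclass
class LCMVFilters:
    weights: np.ndarray  # V x sensors
    valid: np.ndarray  # V bool
    regularization: float
    orientations: np.ndarray | None = None  # V x 3 for vector lead fields


def _scalar_leadfield(leadfield: np.ndarray, c_inv: np.ndarray):
    """Collapse a vector lead field to the power-maximizing orientation.

    The constrained power matrix is P = (L^T Ci L)^+; the power-maximizing
    orientation is its dominant eigenvector.  The pseudoinverse restricts the
    search to orientations the lead field can actually express, which matters
    when the three columns are not linearly independent.
    """
    n_sens, n_vox, _ = leadfield.shape
    scalar = np.empty((n_sens, n_vox))
    orients = np.empty((n_vox, 3))
    for v in range(n_vox):
        L = leadfield[:, v, :]
        P = np.linalg.pinv(L.T @ c_inv @ L, hermitian=True)
        w_eigvals, w_eigvecs = np.linalg.eigh(P)
        u = w_eigvecs[:, -1]
        orients[v] = u
        scalar[:, v] = L @ u
    return scalar, orients


def lcmv_filters(
    leadfield: np.ndarray,
    covariance: np.ndarray,
    regularization: float | None = None,
) -> LCMVFilters:
    """Unit-gain minimum-variance spatial filter per voxel.

    w_v = (L_v^T (C + lam I)^-1 L_v)^-1 L_v^T (C + lam I)^-1, which satisfies
    w_v^T L_v = 1 exactly.  ``regularization`` defaults to 5% of the mean
    sensor variance.  Voxels with a numerically singular constrained system
    are marked invalid and skipped.
    """
    leadfield = np.asarray(leadfield, dtype=float)
    C = np.asarray(covariance, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance must be symmetric")
    n_sens = C.shape[0]
    lam = regularization
    if lam is None:
        lam = 0.05 * float(np.trace(C)) / n_sens
    if lam < 0:
        raise ValueError("regularization must be >= 0")
    c_inv = np.linalg.inv(C + lam * np.eye(n_sens))

    orientations = None
    if leadfield.ndim == 3:
        leadfield, orientations = _scalar_leadfield(leadfield, c_inv)

    n_vox = leadfield.shape[1]
    weights = np.zeros((n_vox, n_sens))
    valid = np.zeros(n_vox, dtype=bool)
    ci_L = c_inv @ leadfield  # sensors x V
    denom = np.einsum("cv,cv->v", leadfield, ci_L)
    scale = np.abs(denom).max() if n_vox else 1.0
    for v in range(n_vox):
        if np.abs(denom[v]) < 1e-12 * max(scale, 1e-30):
            continue
        weights[v] = ci_L[:, v] / denom[v]
        valid[v] = True
    return LCMVFilters(weights=weights, valid=valid, regularization=lam,
                       orientations=orientations)


def condition_filters(
    leadfield: np.ndarray,
    common: LCMVFilters,
    condition_data: dict[str, np.ndarray],
) -> dict[str, LCMVFilters]:
    """Per-condition filters sharing the common solution's settings.

    Each condition's covariance is computed from that condition's epochs
    (trials x channels x samples or channels x samples), while the
    regularization — and, for vector lead fields, the orientation — is
    inherited from the common filter.
    """
    leadfield = np.asarray(leadfield, dtype=float)
    if leadfield.ndim == 3:
        if common.orientations is None:
            raise ValueError("common filter lacks orientations for a vector lead field")
        leadfield = np.einsum("cvd,vd->cv", leadfield, common.orientations)
    out = {}
    for name, data in condition_data.items():
        data = np.asarray(data, dtype=float)
        if data.size == 0:
            raise ValueError(f"condition {name!r} has no data")
        if data.ndim == 3:
            data = np.concatenate(list(data), axis=1)
        C = np.cov(data)
        out[name] = lcmv_filters(leadfield, C, regularization=common.regularization)
    return out


def neural_activity_index(
    filters: LCMVFilters,
    covariance: np.ndarray,
    noise_power: float | None = None,
) -> np.ndarray:
    """NAI_v = (w_v^T C w_v) / (sigma^2 w_v^T w_v); invalid voxels get 0.

    ``noise_power`` defaults to the smallest eigenvalue of the covariance,
    the white-noise-floor estimate.  Dividing output power by the projected
    noise power cancels the depth-dependent blowup of the filter norm.
    """
    C = np.asarray(covariance, dtype=float)
    if noise_power is None:
        noise_power = float(np.linalg.eigvalsh(C)[0])
        noise_power = max(noise_power, 1e-15 * float(np.trace(C)))
    if noise_power <= 0:
        raise ValueError("noise power must be > 0")
    W = filters.weights
    power = np.einsum("vc,cd,vd->v", W, C, W)
    norms = np.einsum("vc,vc->v", W, W)
    nai = np.zeros(W.shape[0])
    ok = filters.valid & (norms > 0)
    nai[ok] = power[ok] / (noise_power * norms[ok])
    return nai


def select_top_voxels(
    nai: np.ndarray,
    region_labels: np.ndarray,
    top_fraction: float = 0.02,
) -> np.ndarray:
    """Indices of the ceil(top_fraction * V_labeled) highest-NAI labeled voxels.

    Only voxels with a non-empty label participate; ties break toward the
    lower voxel index for determinism.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    labels = np.asarray(region_labels, dtype=object)
    labeled = np.flatnonzero(np.array([bool(s) for s in labels]))
    if labeled.size == 0:
        raise ValueError("no labeled voxels")
    k = int(np.ceil(top_fraction * labeled.size))
    order = labeled[np.lexsort((labeled, -np.asarray(nai, dtype=float)[labeled]))]
    return np.sort(order[:k])


def dbscan_cluster(
    voxel_indices: np.ndarray,
    grid: SourceGrid,
    eps_factor: float = 1.5,
    min_pts: int = 2,
) -> tuple[list[VoxelCluster], np.ndarray]:
    """DBSCAN over the retained voxels' positions; returns (clusters, noise).

    eps = ``eps_factor`` x voxel edge length with the Euclidean metric; a
    voxel is core when at least ``min_pts`` retained voxels (itself included)
    lie within eps.  Singleton noise voxels are returned separately.  Each
    cluster is labeled by the majority region label of its members and
    ordered by its smallest member index.
    """
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    if voxel_indices.size == 0:
        return [], np.array([], dtype=int)
    pos = grid.voxel_positions[voxel_indices]
    labels = DBSCAN(eps=eps_factor * grid.voxel_edge_mm, min_samples=min_pts).fit_predict(pos)
    clusters = []
    for cid in sorted(set(labels) - {-1}):
        members = voxel_indices[labels == cid]
        region_names, counts = np.unique(
            grid.region_labels[members].astype(str), return_counts=True
        )
        clusters.append(
            VoxelCluster(
                member_voxels=np.sort(members),
                label=str(region_names[np.argmax(counts)]),
                centroid=grid.voxel_positions[members].mean(axis=0),
            )
        )
    clusters.sort(key=lambda c: int(c.member_voxels[0]))
    noise = np.sort(voxel_indices[labels == -1])
    return clusters, noise


def apply_filters(filters: LCMVFilters, epochs: EpochedSignal) -> np.ndarray:
    """Project sensor epochs through the filters: trials x V x samples."""
    return np.einsum("vc,tcs->tvs", filters.weights, epochs.data)


def cluster_timecourse(cluster: VoxelCluster, voxel_series: np.ndarray,
                       voxel_indices: np.ndarray | None = None) -> np.ndarray:
    """Mean across member voxels, per trial and sample.

    ``voxel_series`` is trials x V x samples over the full grid, or over a
    subset whose grid indices are given by ``voxel_indices``.
    """
    if voxel_indices is None:
        cols = cluster.member_voxels
    else:
        lookup = {int(v): i for i, v in enumerate(voxel_indices)}
        cols = np.array([lookup[int(v)] for v in cluster.member_voxels])
    return voxel_series[:, cols, :].mean(axis=1)


def localize(
    epochs: EpochedSignal,
    grid: SourceGrid,
    top_fraction: float = 0.02,
    eps_factor: float = 1.5,
    min_pts: int = 2,
    regularization: float | None = None,
) -> tuple[list[VoxelCluster], LCMVFilters, np.ndarray]:
    """Full stage: LCMV -> NAI -> top-fraction threshold -> DBSCAN -> time courses.

    Returns the clusters (time courses filled in), the filters, and the NAI
    values per voxel.
    """
    data2d = np.concatenate(list(epochs.data), axis=1)
    C = np.cov(data2d)
    filters = lcmv_filters(grid.leadfield, C, regularization=regularization)
    nai = neural_activity_index(filters, C)
    top = select_top_voxels(nai, grid.region_labels, top_fraction)
    clusters, _ = dbscan_cluster(top, grid, eps_factor=eps_factor, min_pts=min_pts)
    if clusters:
        union = np.unique(np.concatenate([c.member_voxels for c in clusters]))
        sub = LCMVFilters(
            weights=filters.weights[union], valid=filters.valid[union],
            regularization=filters.regularization,
        )
        series = apply_filters(sub, epochs)
        for c in clusters:
            c.timecourse = cluster_timecourse(c, series, voxel_indices=union)
    return clusters, filters, nai


def cluster_table(clusters: list[VoxelCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": i,
                "label": c.label,
                "n_voxels": c.size,
                "centroid_x": float(c.centroid[0]),
                "centroid_y": float(c.centroid[1]),
                "centroid_z": float(c.centroid[2]),
            }
            for i, c in enumerate(clusters)
        ],
        columns=["cluster", "label", "n_voxels", "centroid_x", "centroid_y", "centroid_z"],
    )
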