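"""Dihedral and Cartesian PCA, free-energy landscapes and density clustering.

dPCA works on the periodicity-safe (cos phi, sin phi, cos psi, sin psi)
transform of the backbone dihedrals.  cPCA superposes every frame twice —
onto the first frame, then onto the average structure — with Kabsch
optimal rotations before diagonalising the coordinate covariance, so only
internal motion enters the eigenmodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .amd import FrameWeights, PMFGrid, reweight_histogram
from .constants import DEFAULT_TEMPERATURE
from .dihedrals import DihedralSeries
from .trajectory import TrajectorySet


@dataclass
class PCModel:
    """Eigendecomposition of a coordinate covariance matrix.

    ``eigenvectors[:, k]`` is the k-th mode (descending eigenvalue);
    ``projections`` holds the centred data projected on every mode.
    """

    kind: str
    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    segments: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:  # e.g. purely rigid-body motion after fitting
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]


def _eigendecompose(data: np.ndarray, kind: str, segments: np.ndarray) -> PCModel:
    if data.shape[0] < 3:
        raise ValueError("need at least 3 frames for a covariance analysis")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centered @ evecs
    return PCModel(kind, mean, evals, evecs, projections, segments)


def dpca(series: DihedralSeries, segments: Optional[np.ndarray] = None) -> PCModel:
    """PCA on sin/cos-transformed phi/psi of all fully defined residues."""
    mask = series.defined_mask()
    if mask.sum() < 1:
        raise ValueError("no residue has both angles defined in every frame")
    phi = np.radians(series.phi[:, mask])
    psi = np.radians(series.psi[:, mask])
    data = np.concatenate(
        [np.cos(phi), np.sin(phi), np.cos(psi), np.sin(psi)], axis=1
    )
    if np.allclose(data.var(axis=0), 0.0, atol=1e-14):
        raise ValueError("constant dihedral series: covariance is zero")
    if segments is None:
        segments = np.zeros(data.shape[0], dtype=int)
    return _eigendecompose(data, "dihedral_sincos", np.asarray(segments))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix (proper, via SVD) aligning centred ``mobile``
    onto centred ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def superpose(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares fit every frame onto a reference structure."""
    ref_center = reference.mean(axis=0)
    ref0 = reference - ref_center
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        frame = coords[f] - coords[f].mean(axis=0)
        rot = kabsch_rotation(frame, ref0)
        out[f] = frame @ rot + ref_center
    return out


def cpca(
    traj: TrajectorySet,
    atom_selection: Optional[np.ndarray] = None,
    segments: Optional[np.ndarray] = None,
) -> PCModel:
    """Cartesian PCA after the two-pass superposition.

    Default selection: backbone heavy atoms (N, CA, C, O).
    """
    if atom_selection is None:
        atom_selection = np.isin(traj.atom_names, ("N", "CA", "C", "O"))
    atom_selection = np.asarray(atom_selection)
    if atom_selection.dtype == bool:
        idx = np.flatnonzero(atom_selection)
    else:
        idx = atom_selection.astype(int)
    if idx.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    coords = traj.coords[:, idx, :]
    fitted = superpose(coords, coords[0])
    average = fitted.mean(axis=0)
    fitted = superpose(fitted, average)
    data = fitted.reshape(fitted.shape[0], -1)
    if segments is None:
        segments = traj.segments
    return _eigendecompose(data, "cartesian", np.asarray(segments))


def fel(
    model: PCModel,
    weights: FrameWeights,
    components: tuple = (1, 2),
    bins: int = 72,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PMFGrid:
    """Reweighted free-energy landscape over two principal components."""
    k1, k2 = components
    n_modes = model.projections.shape[1]
    if not (1 <= k1 <= n_modes and 1 <= k2 <= n_modes):
        raise ValueError(f"components {components} outside available modes (1..{n_modes})")
    data = model.projections[:, [k1 - 1, k2 - 1]]
    return reweight_histogram(
        data, weights, bins=bins, temperature=temperature,
        axis_names=(f"PC{k1}", f"PC{k2}"),
    )


@dataclass
class ClusterAssignment:
    """Frame labels from density-peak picking in PC space.

    Cluster ids are 1-based in descending occupancy; 0 marks unassigned
    frames.
    """

    labels: np.ndarray
    occupancies: np.ndarray
    representative_frames: np.ndarray
    peak_coordinates: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.occupancies.shape[0]


def density_cluster(
    model: PCModel,
    n_components: int = 3,
    bins: int = 50,
    threshold: float = 0.1,
) -> ClusterAssignment:
    """Histogram-density peak clustering on the top principal components.

    Bins with density at or above ``threshold * max_density`` form
    superlevel islands; each connected island is one cluster whose peak is
    its densest bin.  Frames falling inside an island join its cluster;
    frames within two grid cells (Chebyshev) of an island join the nearest
    one; everything else stays unassigned.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if n_components > model.projections.shape[1]:
        raise ValueError("n_components exceeds available PCs")
    pts = model.projections[:, :n_components]
    hist, edges = np.histogramdd(pts, bins=bins)
    structure = np.ones((3,) * n_components)
    island_mask = hist >= threshold * hist.max()
    islands, n_islands = ndimage.label(island_mask, structure=structure)
    centers = [(e[:-1] + e[1:]) / 2.0 for e in edges]
    peak_bins = []
    for li in range(1, n_islands + 1):
        members = np.argwhere(islands == li)
        dens = hist[tuple(members.T)]
        peak_bins.append(members[int(np.argmax(dens))])
    peak_bins = np.array(peak_bins)
    peak_coords = np.array(
        [[centers[d][b[d]] for d in range(n_components)] for b in peak_bins]
    )

    frame_bins = np.stack(
        [
            np.clip(np.digitize(pts[:, d], edges[d]) - 1, 0, bins - 1)
            for d in range(n_components)
        ],
        axis=1,
    )
    raw = islands[tuple(frame_bins.T)]
    # frames just outside an island: adopt the nearest island within 2 cells
    dist_cells, nearest_idx = ndimage.distance_transform_cdt(
        islands == 0, metric="chessboard", return_indices=True
    )
    outside = raw == 0
    fb = frame_bins[outside]
    cell_dist = dist_cells[tuple(fb.T)]
    nearest_cell = nearest_idx[(slice(None),) + tuple(fb.T)]
    nearest_lbl = islands[tuple(nearest_cell)]
    raw[outside] = np.where(cell_dist <= 2, nearest_lbl, 0)

    # order clusters by descending occupancy
    occ_raw = np.array([(raw == k + 1).mean() for k in range(n_islands)])
    order = np.argsort(occ_raw)[::-1]
    relabel = np.zeros(n_islands + 1, dtype=int)
    for new_id, old in enumerate(order, start=1):
        relabel[old + 1] = new_id
    labels = relabel[raw]
    occupancies = occ_raw[order]
    peak_coords = peak_coords[order]
    reps = np.full(order.size, -1, dtype=int)
    for k in range(order.size):
        members = np.flatnonzero(labels == k + 1)
        if members.size:
            d = np.linalg.norm(pts[members] - peak_coords[k], axis=1)
            reps[k] = members[int(np.argmin(d))]
    return ClusterAssignment(labels, occupancies, reps, peak_coords)


def cluster_timeline(assign: ClusterAssignment, frame_times: np.ndarray):
    """Per-frame label series plus a transition-count matrix.

    Transitions are counted between consecutive frames whose labels are
    both assigned (non-zero) and differ.  Returns ``(times, labels,
    transition_matrix)`` where the matrix is indexed by cluster id
    (row = from, column = to, 1-based ids at offset-1 positions).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    labels = assign.labels
    if frame_times.shape[0] != labels.shape[0]:
        raise ValueError("frame_times length must equal number of frames")
    if np.any(np.diff(frame_times) < 0):
        raise ValueError("frame_times must be monotone non-decreasing")
    n = assign.n_clusters
    trans = np.zeros((n, n), dtype=int)
    prev = labels[:-1]
    nxt = labels[1:]
    valid = (prev > 0) & (nxt > 0) & (prev != nxt)
    for a, b in zip(prev[valid], nxt[valid]):
        trans[a - 1, b - 1] += 1
    return frame_times, labels, trans
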