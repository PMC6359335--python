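"""Backbone dihedral extraction and Ramachandran-region classification.

Conventions: IUPAC phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1), degrees
wrapped to [-180, 180).  phi is undefined for the first residue (no
preceding carbonyl carbon) and psi for the last (no following amide
nitrogen); undefined angles are stored as NaN, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .amd import FrameWeights, PMFGrid, reweight_histogram
from .constants import DEFAULT_TEMPERATURE
from .trajectory import TrajectorySet


def wrap_angle(a):
    """Wrap angle(s) to [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class DihedralSeries:
    """Per-frame, per-residue (phi, psi) in degrees; NaN marks undefined."""

    res_ids: np.ndarray  # (n_res,), 1-based
    phi: np.ndarray      # (n_frames, n_res)
    psi: np.ndarray      # (n_frames, n_res)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have equal shape")
        if self.phi.shape[1] != self.res_ids.shape[0]:
            raise ValueError("second axis must match number of residues")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_res(self) -> int:
        return self.res_ids.shape[0]

    def residue(self, res_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(phi, psi) series for one residue id."""
        pos = np.flatnonzero(self.res_ids == res_id)
        if not pos.size:
            raise ValueError(f"residue {res_id} not in series")
        j = int(pos[0])
        return self.phi[:, j], self.psi[:, j]

    def defined_mask(self) -> np.ndarray:
        """(n_res,) True where both angles are defined in every frame."""
        return ~(np.isnan(self.phi).any(axis=0) | np.isnan(self.psi).any(axis=0))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns frame, residue, phi, psi."""
        frames, cols = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_res), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "residue": self.res_ids[cols.ravel()],
                "phi": self.phi.ravel(),
                "psi": self.psi.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DihedralSeries":
        res_ids = np.unique(df["residue"].to_numpy())
        pivot_phi = df.pivot(index="frame", columns="residue", values="phi")
        pivot_psi = df.pivot(index="frame", columns="residue", values="psi")
        return cls(res_ids, pivot_phi.to_numpy(), pivot_psi.to_numpy())


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (deg) of four points; vectorised over leading axes.

    Raises on degenerate geometry (collinear bonded triples give a zero
    normal and an undefined torsion).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    if np.any(np.linalg.norm(v, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(w, axis=-1) < 1e-10
    ):
        raise ValueError("degenerate dihedral: collinear atoms")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def compute_dihedrals(traj: TrajectorySet) -> DihedralSeries:
    """Extract phi/psi per residue per frame from backbone coordinates."""
    res_ids = traj.residue_ids
    n_frames = traj.n_frames
    phi = np.full((n_frames, res_ids.size), np.nan)
    psi = np.full((n_frames, res_ids.size), np.nan)
    backbone = {}
    for rid in res_ids:
        for name in ("N", "CA", "C"):
            idx = traj.atom_index(int(rid), name)
            if idx < 0:
                raise ValueError(f"residue {rid}: backbone atom {name!r} missing")
            backbone[(int(rid), name)] = traj.coords[:, idx, :]
    id_set = set(int(r) for r in res_ids)
    for j, rid in enumerate(int(r) for r in res_ids):
        if rid - 1 in id_set:
            phi[:, j] = dihedral_angle(
                backbone[(rid - 1, "C")],
                backbone[(rid, "N")],
                backbone[(rid, "CA")],
                backbone[(rid, "C")],
            )
        if rid + 1 in id_set:
            psi[:, j] = dihedral_angle(
                backbone[(rid, "N")],
                backbone[(rid, "CA")],
                backbone[(rid, "C")],
                backbone[(rid + 1, "N")],
            )
    return DihedralSeries(res_ids, phi, psi)


# Ramachandran region centers (phi, psi) in degrees.  The left-handed
# helix center is the mirror image of the right-handed one; the beta
# mirror is used only for the delta' bridge test.
REGION_CENTERS = {
    "alpha_R": (-63.0, -43.0),
    "alpha_L": (63.0, 43.0),
    "beta": (-157.2, 161.9),
    "PII": (-65.0, 145.0),
    "gamma": (80.0, -80.0),
    "gamma_prime": (-80.0, 80.0),
    "zeta": (-130.0, 80.0),
}

_BETA_MIRROR = (157.2, -161.9)

#: Bridge-band width (deg) for the delta/delta' assignment: a point whose
#: nearest center is the alpha helix but whose distance to the beta center
#: is within this margin of the alpha distance sits in the alpha/beta
#: bridge.
DELTA_BAND = 25.0

REGION_LABELS = list(REGION_CENTERS) + ["delta", "delta_prime", "unassigned"]


def _periodic_dist(phi, psi, center):
    d0 = wrap_angle(np.asarray(phi, dtype=float) - center[0])
    d1 = wrap_angle(np.asarray(psi, dtype=float) - center[1])
    return np.hypot(d0, d1)


def classify_regions(phi, psi, delta_band: float = DELTA_BAND) -> np.ndarray:
    """Vectorised nearest-center Ramachandran labels with the delta bridge.

    Every (phi, psi) pair receives exactly one label; the assignment is
    invariant under 360-degree shifts.  Ties go to the earlier center in
    the tabulated order.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    names = list(REGION_CENTERS)
    dists = np.stack([_periodic_dist(phi, psi, REGION_CENTERS[n]) for n in names])
    nearest = np.argmin(dists, axis=0)  # argmin takes the first on ties
    labels = np.array(names, dtype="U16")[nearest]
    d_alpha_r = dists[names.index("alpha_R")]
    d_alpha_l = dists[names.index("alpha_L")]
    d_beta = dists[names.index("beta")]
    d_beta_m = _periodic_dist(phi, psi, _BETA_MIRROR)
    labels[(labels == "alpha_R") & (d_beta - d_alpha_r <= delta_band)] = "delta"
    labels[(labels == "alpha_L") & (d_beta_m - d_alpha_l <= delta_band)] = "delta_prime"
    return labels


def classify_region(phi: float, psi: float, delta_band: float = DELTA_BAND) -> str:
    """Scalar convenience wrapper around :func:`classify_regions`."""
    return str(classify_regions([phi], [psi], delta_band=delta_band)[0])


def residue_pmf_map(
    series: DihedralSeries,
    weights: FrameWeights,
    residue: int,
    bins: int = 72,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PMFGrid:
    """Reweighted 2D phi/psi PMF map for one residue."""
    phi, psi = series.residue(residue)
    if np.isnan(phi).any() or np.isnan(psi).any():
        raise ValueError(
            f"residue {residue} has undefined phi or psi (chain end); no map"
        )
    data = np.column_stack([phi, psi])
    return reweight_histogram(
        data,
        weights,
        bins=bins,
        hist_range=[[-180.0, 180.0], [-180.0, 180.0]],
        temperature=temperature,
        axis_names=("phi", "psi"),
    )


def region_occupancy(series: DihedralSeries, weights: Optional[FrameWeights] = None) -> pd.DataFrame:
    """Residue x region weighted occupancy fractions.

    Residues missing one of the angles (chain ends) are skipped.
    """
    w = np.ones(series.n_frames) if weights is None else weights.weights
    if weights is not None and weights.estimator == "cumulant2":
        w = np.ones(series.n_frames)  # raw dV is not a frame weight
    rows = {}
    for j, rid in enumerate(series.res_ids):
        phi, psi = series.phi[:, j], series.psi[:, j]
        if np.isnan(phi).any() or np.isnan(psi).any():
            continue
        labels = classify_regions(phi, psi)
        total = w.sum()
        rows[int(rid)] = {
            lab: w[labels == lab].sum() / total for lab in REGION_LABELS[:-1]
        }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df.index.name = "residue"
    return df
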