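"""Ground-truth synthetic systems for exercising the analysis stack.

Three generators stand in for an MD engine:

* a Metropolis Monte Carlo sampler on analytic 2D periodic potentials,
  optionally run on the aMD-boosted surface ``V + dV(V)`` with the boost
  logged per frame — the stationary distribution is then exactly
  ``exp(-(V + dV)/kT)``, which is all the reweighting machinery needs;
* an internal-to-Cartesian toy peptide backbone builder (NeRF chain
  extension with ideal bond geometry) so coordinate-based operations have
  inputs with known dihedrals;
* multi-replica samplers with controllable overlap for convergence
  analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .amd import AMDParameters, BoostLog, boost_energy
from .constants import DEFAULT_TEMPERATURE, kt
from .dihedrals import DihedralSeries, wrap_angle
from .trajectory import TrajectorySet


@dataclass
class ModelPotential:
    """Periodic 2D potential as a sum of inverted Gaussian basins.

    ``V(x, y) = -sum_k depth_k * exp(-(dx_k^2 + dy_k^2) / (2 width_k^2))``
    with minimum-image differences, hence 360-degree periodicity on each
    axis.  The analytic PMF is ``V - min V``.
    """

    kind: str
    centers: tuple  # ((phi, psi), ...) in degrees
    depths: tuple   # kcal/mol, positive = basin depth
    widths: tuple   # degrees

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.depths) == len(self.widths)):
            raise ValueError("centers, depths, widths must have equal length")
        if any(d <= 0 for d in self.depths) or any(w <= 0 for w in self.widths):
            raise ValueError("depths and widths must be positive")

    def energy(self, phi, psi) -> np.ndarray:
        """Potential energy (kcal/mol); vectorised."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        v = np.zeros(np.broadcast(phi, psi).shape)
        for (cx, cy), d, w in zip(self.centers, self.depths, self.widths):
            dx = wrap_angle(phi - cx)
            dy = wrap_angle(psi - cy)
            v = v - d * np.exp(-(dx * dx + dy * dy) / (2.0 * w * w))
        return v

    def analytic_pmf(self, phi_grid: np.ndarray, psi_grid: np.ndarray) -> np.ndarray:
        """V - min(V) evaluated on the outer product of two degree grids."""
        v = self.energy(phi_grid[:, None], psi_grid[None, :])
        return v - v.min()

    def basin_center(self, k: int = 0) -> tuple:
        return self.centers[k]


def double_well(
    centers=((-63.0, -43.0), (-157.0, 161.0)),
    depths=(6.0, 4.0),
    width=30.0,
) -> ModelPotential:
    """Two-basin periodic potential; defaults put a ~6 kcal/mol barrier
    between a helical and an extended well, bracketing the few-kcal/mol
    barriers typical of short-peptide landscapes."""
    return ModelPotential(
        "double_well_periodic", tuple(centers), tuple(depths), (width, width)
    )


def single_basin(center=(-63.0, -43.0), depth=5.0, width=30.0) -> ModelPotential:
    return ModelPotential("gaussian_basins", (tuple(center),), (depth,), (width,))


@dataclass
class SamplerConfig:
    """Metropolis sampler settings; the seed fixes the run bit-for-bit."""

    n_steps: int
    seed: int
    temperature: float = DEFAULT_TEMPERATURE
    step_size: float = 10.0
    record_stride: int = 1
    boost: Optional[AMDParameters] = None
    start: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


def dihedral_boost(e: float, alpha: float) -> AMDParameters:
    """Dihedral-only boost with explicit threshold/softness, for use on a
    model potential whose energy plays the role of the torsion energy."""
    return AMDParameters(mode="iamd2_dihedral", e_dihed=e, alpha_dihed=alpha)


def sample_biased(
    potential: ModelPotential, config: SamplerConfig
) -> tuple[DihedralSeries, BoostLog]:
    """Metropolis sampling of exp(-(V + dV)/kT) on a 2D periodic potential.

    Gaussian angular proposals with periodic wrapping; one (phi, psi)
    point and its boost energy are recorded every ``record_stride`` steps.
    With ``boost=None`` the chain targets the canonical distribution and
    the log is identically zero.
    """
    boost = config.boost
    if boost is not None:
        if not boost.uses_dihedral or boost.e_dihed is None or boost.alpha_dihed is None:
            raise ValueError("sampler boost must define a dihedral channel (E, alpha)")
        if boost.alpha_dihed <= 0:
            raise ValueError("boost alpha must be positive")
        e_thr = float(boost.e_dihed)
        alpha = float(boost.alpha_dihed)
    beta = 1.0 / kt(config.temperature)
    rng = np.random.default_rng(config.seed)
    proposals = rng.normal(0.0, config.step_size, size=(config.n_steps, 2))
    log_u = np.log(rng.random(config.n_steps))

    centers = [(float(c[0]), float(c[1])) for c in potential.centers]
    depths = [float(d) for d in potential.depths]
    inv2w2 = [1.0 / (2.0 * float(w) * float(w)) for w in potential.widths]
    mexp = math.exp

    def v_of(x: float, y: float) -> float:
        s = 0.0
        for (cx, cy), d, iw in zip(centers, depths, inv2w2):
            dx = (x - cx + 180.0) % 360.0 - 180.0
            dy = (y - cy + 180.0) % 360.0 - 180.0
            s -= d * mexp(-(dx * dx + dy * dy) * iw)
        return s

    if boost is not None:
        def dv_of(v: float) -> float:
            if v >= e_thr:
                return 0.0
            diff = e_thr - v
            return diff * diff / (alpha + diff)
    else:
        def dv_of(v: float) -> float:
            return 0.0

    x, y = config.start if config.start is not None else centers[0]
    x = (x + 180.0) % 360.0 - 180.0
    y = (y + 180.0) % 360.0 - 180.0
    v = v_of(x, y)
    vstar = v + dv_of(v)
    n_rec = config.n_steps // config.record_stride
    phis = np.empty(n_rec)
    psis = np.empty(n_rec)
    dvs = np.empty(n_rec)
    j = 0
    stride = config.record_stride
    for i in range(config.n_steps):
        xn = (x + proposals[i, 0] + 180.0) % 360.0 - 180.0
        yn = (y + proposals[i, 1] + 180.0) % 360.0 - 180.0
        vn = v_of(xn, yn)
        vsn = vn + dv_of(vn)
        if log_u[i] <= -beta * (vsn - vstar):
            x, y, v, vstar = xn, yn, vn, vsn
        if (i + 1) % stride == 0:
            phis[j] = x
            psis[j] = y
            dvs[j] = vstar - v
            j += 1
    series = DihedralSeries(np.array([1]), phis[:, None], psis[:, None])
    log = BoostLog(dvs, np.zeros_like(dvs), mode="iamd2_dihedral")
    return series, log


def make_replicas(
    potential: ModelPotential,
    n_replicas: int,
    seeds: Sequence[int],
    overlap_mode: str = "same_basin",
    n_steps: int = 100_000,
    temperature: float = DEFAULT_TEMPERATURE,
    step_size: float = 10.0,
    record_stride: int = 1,
) -> list[DihedralSeries]:
    """Independent sampler replicas with controllable overlap.

    ``same_basin`` starts every replica in the deepest basin so their
    stationary distributions agree; ``disjoint_basins`` starts replica k
    in basin k (cycled) — on a potential with inter-basin barriers of
    several kcal/mol the replicas do not mix at the given length.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if len(seeds) < n_replicas:
        raise ValueError(f"need {n_replicas} seeds, got {len(seeds)}")
    if overlap_mode not in ("same_basin", "disjoint_basins"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    if overlap_mode == "disjoint_basins" and len(potential.centers) < 2:
        raise ValueError("disjoint_basins needs a multi-basin potential")
    deepest = int(np.argmax(potential.depths))
    out = []
    for k in range(n_replicas):
        if overlap_mode == "same_basin":
            start = potential.centers[deepest]
        else:
            start = potential.centers[k % len(potential.centers)]
        cfg = SamplerConfig(
            n_steps=n_steps,
            seed=int(seeds[k]),
            temperature=temperature,
            step_size=step_size,
            record_stride=record_stride,
            start=start,
        )
        series, _ = sample_biased(potential, cfg)
        out.append(series)
    return out


# --- toy peptide backbone construction (NeRF chain extension) ---

# Ideal backbone geometry (Angstrom / degrees), Engh–Huber-like values;
# only relative geometry matters for the synthetic tests.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.4
ANGLE_C_N_H = 119.5
OMEGA = 180.0


@dataclass
class ToyChainSpec:
    """Backbone-only peptide frames defined by per-frame (phi, psi) series.

    ``phi_psi`` has shape (n_frames, n_res, 2) in degrees; the first
    residue's phi and the last residue's psi are geometry placeholders
    (they do not correspond to a defined dihedral in the built chain).
    """

    phi_psi: np.ndarray
    res_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.phi_psi = np.asarray(self.phi_psi, dtype=float)
        if self.phi_psi.ndim == 2:
            self.phi_psi = self.phi_psi[None, :, :]
        if self.phi_psi.ndim != 3 or self.phi_psi.shape[2] != 2:
            raise ValueError("phi_psi must have shape (n_frames, n_res, 2)")
        if self.phi_psi.shape[1] < 2:
            raise ValueError("need at least 2 residues")
        if self.res_names is not None and len(self.res_names) != self.phi_psi.shape[1]:
            raise ValueError("res_names length must equal n_res")

    @property
    def n_res(self) -> int:
        return self.phi_psi.shape[1]

    @property
    def n_frames(self) -> int:
        return self.phi_psi.shape[0]


def helix_spec(n_res: int, n_frames: int = 1, phi=-63.0, psi=-43.0,
               jitter: float = 0.0, seed: int = 0,
               res_names: Optional[Sequence[str]] = None) -> ToyChainSpec:
    """Uniform (phi, psi) chain, optionally with Gaussian angular jitter."""
    base = np.tile(np.array([[phi, psi]]), (n_res, 1))[None, :, :]
    pp = np.tile(base, (n_frames, 1, 1))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pp = wrap_angle(pp + rng.normal(0.0, jitter, size=pp.shape))
    return ToyChainSpec(pp, res_names=res_names)


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle,
    torsion(a,b,c,d) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_chain(spec: ToyChainSpec) -> TrajectorySet:
    """Build backbone atoms (N, CA, C, O and amide H) frame by frame.

    Recomputing phi/psi from the output recovers the input series for all
    defined angles.  Residue 1 has no amide H (no preceding carbonyl to
    orient it against) and the chain carries no terminal extras.
    """
    n_res = spec.n_res
    names = []
    res_ids = []
    for i in range(1, n_res + 1):
        for nm in ("N", "CA", "C", "O") + (("H",) if i > 1 else ()):
            names.append(nm)
            res_ids.append(i)
    names = np.array(names)
    res_ids = np.array(res_ids)
    res_names = (
        np.array([spec.res_names[i - 1] for i in res_ids])
        if spec.res_names is not None
        else np.full(res_ids.shape, "ALA", dtype="U6")
    )
    coords = np.empty((spec.n_frames, names.size, 3))
    lookup = {(int(r), str(n)): k for k, (r, n) in enumerate(zip(res_ids, names))}

    for f in range(spec.n_frames):
        pp = spec.phi_psi[f]
        pos = {}
        pos[(1, "N")] = np.zeros(3)
        pos[(1, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
        ang = math.radians(ANGLE_N_CA_C)
        pos[(1, "C")] = pos[(1, "CA")] + BOND_CA_C * np.array(
            [-math.cos(ang), math.sin(ang), 0.0]
        )
        for i in range(2, n_res + 1):
            psi_prev = pp[i - 2, 1]
            pos[(i, "N")] = _place(
                pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
                BOND_C_N, ANGLE_CA_C_N, psi_prev,
            )
            pos[(i, "CA")] = _place(
                pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
                BOND_N_CA, ANGLE_C_N_CA, OMEGA,
            )
            pos[(i, "C")] = _place(
                pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
                BOND_CA_C, ANGLE_N_CA_C, pp[i - 1, 0],
            )
            # amide H in the peptide plane, anti to the carbonyl O
            pos[(i, "H")] = _place(
                pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
                BOND_N_H, ANGLE_C_N_H, 0.0,
            )
        for i in range(1, n_res + 1):
            psi_i = pp[i - 1, 1] if i < n_res else 0.0
            pos[(i, "O")] = _place(
                pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0,
            )
        for key, k in lookup.items():
            coords[f, k] = pos[key]
    return TrajectorySet(coords, names, res_ids, res_names)
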