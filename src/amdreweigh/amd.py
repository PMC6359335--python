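"""Accelerated-MD boost parameterisation and ensemble reweighting.

aMD adds a non-negative boost ``dV(V) = (E - V)^2 / (alpha + E - V)`` to
the potential whenever the instantaneous potential energy ``V`` falls
below the threshold ``E``, flattening barriers.  The modified ensemble is
reweighted back to the canonical one by the per-frame Boltzmann factor
``exp(dV / kT)``, or by numerically gentler approximations of it
(truncated Maclaurin series; bin-wise second-order cumulant expansion).

Boost thresholds follow the standard per-system parameterisation

    E_dihed = V_avg_dihed + a1 * N_res      alpha_dihed = a2 * N_res / 5
    E_total = V_avg_total + b1 * N_atoms    alpha_total = b2 * N_atoms

where the averages come from a short unbiased run, ``N_res`` counts
peptide residues and ``N_atoms`` all atoms in the system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt

#: Boost modes: total-potential boost only, dihedral-only boost, or dual.
MODES = ("iamd1_total", "iamd2_dihedral", "iamd3_dual")


@dataclass
class AMDParameters:
    """Boost thresholds/softness for the active channels.

    Channels not used by ``mode`` keep ``E``/``alpha`` as ``None``.
    """

    mode: str
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    n_res: int = 0
    n_atoms: int = 0
    v_avg_dihed: float = 0.0
    v_avg_total: float = 0.0
    e_dihed: Optional[float] = None
    alpha_dihed: Optional[float] = None
    e_total: Optional[float] = None
    alpha_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.uses_dihedral and self.alpha_dihed is not None and self.alpha_dihed <= 0:
            raise ValueError("alpha_dihed must be positive for an active dihedral boost")
        if self.uses_total and self.alpha_total is not None and self.alpha_total <= 0:
            raise ValueError("alpha_total must be positive for an active total boost")

    @property
    def uses_dihedral(self) -> bool:
        return self.mode in ("iamd2_dihedral", "iamd3_dual")

    @property
    def uses_total(self) -> bool:
        return self.mode in ("iamd1_total", "iamd3_dual")


def compute_boost_parameters(
    a1: float,
    a2: float,
    b1: float,
    b2: float,
    n_res: int,
    n_atoms: int,
    v_avg_dihed: float,
    v_avg_total: float,
    mode: str,
) -> AMDParameters:
    """Derive boost thresholds E and softness alpha from the coefficients.

    Raises if an active channel has a zero coefficient (alpha would
    vanish and the boost be ill-defined).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if n_res <= 0 or n_atoms <= 0:
        raise ValueError("n_res and n_atoms must be positive counts")
    if min(a1, a2, b1, b2) < 0:
        raise ValueError("boost coefficients must be non-negative")
    params = AMDParameters(
        mode=mode, a1=a1, a2=a2, b1=b1, b2=b2, n_res=n_res, n_atoms=n_atoms,
        v_avg_dihed=v_avg_dihed, v_avg_total=v_avg_total,
    )
    if params.uses_dihedral:
        if a1 == 0 or a2 == 0:
            raise ValueError(f"mode {mode} needs a1, a2 > 0 (alpha_dihed would be 0)")
        params.e_dihed = v_avg_dihed + a1 * n_res
        params.alpha_dihed = a2 * n_res / 5.0
    if params.uses_total:
        if b1 == 0 or b2 == 0:
            raise ValueError(f"mode {mode} needs b1, b2 > 0 (alpha_total would be 0)")
        params.e_total = v_avg_total + b1 * n_atoms
        params.alpha_total = b2 * n_atoms
    return params


def boost_energy(v, e: float, alpha: float):
    """aMD boost dV = (E - V)^2 / (alpha + E - V) for V < E, else 0.

    Accepts scalars or arrays; continuous at ``V = E`` and monotonically
    decreasing in ``V`` below the threshold.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    v_arr = np.asarray(v, dtype=float)
    diff = e - v_arr
    with np.errstate(invalid="ignore"):
        dv = np.where(diff > 0, diff * diff / (alpha + diff), 0.0)
    if np.isscalar(v) or v_arr.ndim == 0:
        return float(dv)
    return dv


@dataclass
class BoostLog:
    """Per-frame boost energies, mirroring the role of Amber's amd.log.

    ``dv`` is the effective total bias used in reweighting: the sum of
    both channels for a dual boost, and the single active channel
    otherwise.
    """

    dv_dihed: np.ndarray
    dv_total: np.ndarray
    mode: str = "iamd3_dual"

    def __post_init__(self) -> None:
        self.dv_dihed = np.asarray(self.dv_dihed, dtype=float)
        self.dv_total = np.asarray(self.dv_total, dtype=float)
        if self.dv_dihed.shape != self.dv_total.shape:
            raise ValueError("dv_dihed and dv_total must have equal length")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, arr in (("dv_dihed", self.dv_dihed), ("dv_total", self.dv_total)):
            bad = np.flatnonzero(arr < 0)
            if bad.size:
                raise ValueError(
                    f"negative {name} at frame {bad[0]}: boost energies must be >= 0"
                )

    def __len__(self) -> int:
        return self.dv_dihed.shape[0]

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self), dtype=int)

    @property
    def dv(self) -> np.ndarray:
        if self.mode == "iamd2_dihedral":
            return self.dv_dihed
        if self.mode == "iamd1_total":
            return self.dv_total
        return self.dv_dihed + self.dv_total

    @classmethod
    def zeros(cls, n_frames: int, mode: str = "iamd3_dual") -> "BoostLog":
        return cls(np.zeros(n_frames), np.zeros(n_frames), mode=mode)


ESTIMATORS = ("exponential", "maclaurin", "cumulant2")


@dataclass
class FrameWeights:
    """Per-frame reweighting factors.

    For ``exponential`` and ``maclaurin`` the ``weights`` array holds the
    (approximate) Boltzmann factors.  For ``cumulant2`` the expansion is
    applied bin-wise inside :func:`reweight_histogram`, so ``weights``
    passes the raw boost energies (kcal/mol) through.
    """

    estimator: str
    weights: np.ndarray
    order: int = 0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def uniform(cls, n_frames: int, temperature: float = DEFAULT_TEMPERATURE) -> "FrameWeights":
        return cls("exponential", np.ones(n_frames), temperature=temperature)


def maclaurin_factors(x: np.ndarray, order: int) -> np.ndarray:
    """Truncated Maclaurin series of exp(x): sum_{j<=order} x^j / j!."""
    out = np.ones_like(x)
    term = np.ones_like(x)
    for j in range(1, order + 1):
        term = term * x / j
        out = out + term
    return out


def compute_weights(
    log: BoostLog,
    temperature: float = DEFAULT_TEMPERATURE,
    estimator: str = "maclaurin",
    order: int = 10,
) -> FrameWeights:
    """Turn a boost log into per-frame reweighting factors.

    ``maclaurin`` with ``order=10`` is the default estimator; the exact
    exponential is retained for cross-checks; ``cumulant2`` defers to the
    bin-wise expansion in :func:`reweight_histogram`.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    dv = log.dv
    if np.any(dv < 0):
        raise ValueError("boost log contains negative dV (corrupt log)")
    if estimator == "cumulant2":
        return FrameWeights("cumulant2", dv.copy(), temperature=temperature)
    x = dv / kt(temperature)
    if estimator == "exponential":
        w = np.exp(x)
    else:
        if order < 1:
            raise ValueError("maclaurin order must be >= 1")
        w = maclaurin_factors(x, order)
    return FrameWeights(estimator, w, order=order, temperature=temperature)


@dataclass
class PMFGrid:
    """Binned potential of mean force, mu = -kT ln P, minimum anchored at 0.

    Empty bins are masked (NaN in ``pmf``), never reported as zero free
    energy.  ``prob`` is normalised over populated bins.
    """

    edges: list
    prob: np.ndarray
    pmf: np.ndarray
    mask: np.ndarray
    temperature: float
    axis_names: tuple = ()

    @property
    def centers(self) -> list:
        return [(e[:-1] + e[1:]) / 2.0 for e in self.edges]

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def min_bin(self) -> tuple:
        """Multi-index of the global PMF minimum over populated bins."""
        masked = np.where(self.mask, self.pmf, np.inf)
        return np.unravel_index(int(np.argmin(masked)), self.pmf.shape)


def _histogram(series: np.ndarray, bins, hist_range, weights=None):
    if series.ndim == 1:
        counts, edges = np.histogram(series, bins=bins, range=hist_range, weights=weights)
        return counts, [edges]
    counts, e0, e1 = np.histogram2d(
        series[:, 0], series[:, 1], bins=bins, range=hist_range, weights=weights
    )
    return counts, [e0, e1]


def reweight_histogram(
    series: np.ndarray,
    weights: FrameWeights,
    bins=72,
    hist_range=None,
    temperature: float = DEFAULT_TEMPERATURE,
    axis_names: tuple = (),
) -> PMFGrid:
    """Weighted histogram of a 1D or 2D coordinate series as a PMF.

    Bin probabilities are proportional to the summed frame weights; for
    the ``cumulant2`` estimator each bin's biased probability is
    multiplied by ``exp(beta <dV> + beta^2 var(dV) / 2)`` computed from
    the frames it contains.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim not in (1, 2) or (series.ndim == 2 and series.shape[1] != 2):
        raise ValueError("series must be (n,) or (n, 2)")
    if series.shape[0] != len(weights):
        raise ValueError(
            f"series has {series.shape[0]} frames but weights has {len(weights)}"
        )
    beta = 1.0 / kt(temperature)
    if weights.estimator == "cumulant2":
        counts, edges = _histogram(series, bins, hist_range)
        x = beta * weights.weights  # dimensionless boost
        shape = counts.shape
        if series.ndim == 1:
            idx = np.clip(np.digitize(series, edges[0]) - 1, 0, shape[0] - 1)
            flat = idx
        else:
            i0 = np.clip(np.digitize(series[:, 0], edges[0]) - 1, 0, shape[0] - 1)
            i1 = np.clip(np.digitize(series[:, 1], edges[1]) - 1, 0, shape[1] - 1)
            flat = i0 * shape[1] + i1
        s0 = np.bincount(flat, minlength=counts.size).astype(float)
        s1 = np.bincount(flat, weights=x, minlength=counts.size)
        s2 = np.bincount(flat, weights=x * x, minlength=counts.size)
        mask_flat = s0 > 0
        mu = np.zeros_like(s0)
        var = np.zeros_like(s0)
        mu[mask_flat] = s1[mask_flat] / s0[mask_flat]
        var[mask_flat] = s2[mask_flat] / s0[mask_flat] - mu[mask_flat] ** 2
        p = np.where(mask_flat, s0 * np.exp(mu + 0.5 * var), 0.0).reshape(shape)
    else:
        w = weights.weights
        if np.all(w == 0):
            raise ValueError("all frame weights are zero")
        p, edges = _histogram(series, bins, hist_range, weights=w)
    total = p.sum()
    if total <= 0:
        raise ValueError("no populated bins")
    p = p / total
    mask = p > 0
    pmf = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore"):
        pmf[mask] = -kt(temperature) * np.log(p[mask])
    pmf[mask] -= pmf[mask].min()
    return PMFGrid(edges, p, pmf, mask, temperature, axis_names=tuple(axis_names))
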