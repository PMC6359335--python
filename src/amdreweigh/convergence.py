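"""Replica-convergence assessment by Kullback-Leibler divergence.

Principal-component (or any 1D reaction-coordinate) samples from two
replicas are turned into Gaussian-KDE histograms on a shared grid at a
sequence of growing time horizons; the time-dependent divergence

    KLD(t) = sum_i P(t, i) ln(P(t, i) / Q(t, i))

is evaluated over grid points populated by both distributions (after
renormalising over that joint support).  A replica pair is called
converged once KLD stays below the cutoff (default 0.025) through the
end of the data; a later excursion above the cutoff clears the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

#: Default convergence cutoff on the divergence itself.
KLD_CUTOFF = 0.025

#: Density below this (relative to the grid maximum) counts as
#: unpopulated and is excluded from the divergence sum.
_SUPPORT_RTOL = 1e-12


@dataclass
class KDEHistogram:
    """Gaussian-KDE density on a fixed grid, normalised to sum 1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    horizon: int
    segment: int = 0

    @property
    def support(self) -> np.ndarray:
        return self.density > _SUPPORT_RTOL * self.density.max()


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb for a 1D sample."""
    n = samples.shape[0]
    sigma = samples.std(ddof=1)
    if sigma == 0:
        sigma = max(abs(samples[0]) * 1e-3, 1e-6)
    return 1.06 * sigma * n ** (-1 / 5)


def shared_grid(samples: Sequence[np.ndarray], n_points: int = 512) -> np.ndarray:
    """Evaluation grid spanning the union range padded by 3 bandwidths."""
    lo = min(float(np.min(s)) for s in samples)
    hi = max(float(np.max(s)) for s in samples)
    pad = 3.0 * max(silverman_bandwidth(np.asarray(s, dtype=float)) for s in samples)
    if hi - lo + 2 * pad <= 0:
        pad = 1.0
    return np.linspace(lo - pad, hi + pad, n_points)


def kde_histogram(
    samples: np.ndarray,
    horizon: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    bandwidth: Optional[float] = None,
    segment: int = 0,
) -> KDEHistogram:
    """Gaussian-kernel density of the first ``horizon`` samples on a grid.

    ``horizon=None`` uses the full series (prefix semantics otherwise).
    Bandwidth defaults to Silverman's rule on the prefix.
    """
    samples = np.asarray(samples, dtype=float)
    if horizon is not None:
        samples = samples[:horizon]
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(samples)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = shared_grid([samples])
    if samples.std(ddof=1) == 0:
        # degenerate sample: place the kernel by hand
        dens = np.exp(-0.5 * ((grid - samples[0]) / bandwidth) ** 2)
    else:
        kde = gaussian_kde(samples, bw_method=bandwidth / samples.std(ddof=1))
        dens = kde(grid)
    total = dens.sum()
    if total <= 0:
        raise ValueError("density vanished on the supplied grid")
    return KDEHistogram(grid, dens / total, float(bandwidth),
                        int(samples.shape[0]), segment)


def kld(p: KDEHistogram, q: KDEHistogram) -> float:
    """Kullback-Leibler divergence between two gridded densities.

    Evaluated where both densities are populated, after renormalising
    each over that joint support; raises if the supports are disjoint.
    """
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("KLD requires a shared evaluation grid")
    joint = p.support & q.support
    if not joint.any():
        raise ValueError("disjoint supports: divergence undefined")
    pj = p.density[joint]
    qj = q.density[joint]
    pj = pj / pj.sum()
    qj = qj / qj.sum()
    return float(np.sum(pj * np.log(pj / qj)))


@dataclass
class KLDSeries:
    """KLD(t) per replica pair with the convergence verdict."""

    times: np.ndarray           # evaluation horizons (frame counts)
    pairs: list                 # (i, j) replica index pairs
    values: np.ndarray          # (n_pairs, n_times)
    converged: np.ndarray       # per pair
    convergence_time: np.ndarray  # first horizon of sustained sub-cutoff KLD (-1 if none)
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (i, j) in enumerate(self.pairs):
            for t_idx, t in enumerate(self.times):
                rows.append(
                    {
                        "time": int(t),
                        "pair": f"{i + 1}:{j + 1}",
                        "kld": self.values[k, t_idx],
                        "converged": bool(self.converged[k]),
                    }
                )
        return pd.DataFrame(rows)


def kld_timeseries(
    replicas: Sequence[np.ndarray],
    pairs: Optional[Sequence[tuple]] = None,
    eval_fractions: Optional[Sequence[float]] = None,
    cutoff: float = KLD_CUTOFF,
    n_grid: int = 512,
) -> KLDSeries:
    """Time-dependent divergence between replica sample prefixes.

    By default consecutive replicas are paired (0-1, 1-2, ...) and KLD is
    evaluated every 5% of the shortest replica length.  A pair is flagged
    converged at the first horizon after which KLD stays below ``cutoff``
    through the final horizon; the flag is cleared whenever a later value
    rises above the cutoff again.
    """
    replicas = [np.asarray(r, dtype=float).ravel() for r in replicas]
    if len(replicas) < 2:
        raise ValueError("need at least 2 replicas")
    if pairs is None:
        pairs = [(i, i + 1) for i in range(len(replicas) - 1)]
    if eval_fractions is None:
        eval_fractions = np.arange(0.05, 1.0001, 0.05)
    n_min = min(r.shape[0] for r in replicas)
    times = np.unique(np.clip((np.asarray(eval_fractions) * n_min).astype(int), 2, n_min))
    grid = shared_grid(replicas, n_points=n_grid)
    values = np.empty((len(pairs), times.size))
    for k, (i, j) in enumerate(pairs):
        for t_idx, t in enumerate(times):
            p = kde_histogram(replicas[i], horizon=int(t), grid=grid, segment=i)
            q = kde_histogram(replicas[j], horizon=int(t), grid=grid, segment=j)
            try:
                values[k, t_idx] = kld(p, q)
            except ValueError:
                # disjoint supports: no overlap at all, divergence maximal
                values[k, t_idx] = np.inf
    converged = np.zeros(len(pairs), dtype=bool)
    conv_time = np.full(len(pairs), -1, dtype=int)
    for k in range(len(pairs)):
        below = values[k] < cutoff
        if below[-1]:
            # last index from which the run of sub-cutoff values is unbroken
            idx = times.size - 1
            while idx > 0 and below[idx - 1]:
                idx -= 1
            converged[k] = True
            conv_time[k] = times[idx]
    return KLDSeries(times, list(pairs), values, converged, conv_time, cutoff)
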