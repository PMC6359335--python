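"""Readers, writers, run configuration and the end-to-end pipeline.

File dialects
-------------
* trajectories: multi-model PDB (MODEL/ENDMDL), via biotite;
* dihedral series: TSV with columns ``frame  residue  phi  psi``;
* boost logs: TSV with columns ``frame  dV_dihed  dV_total`` (kcal/mol;
  ``dV_total`` optional for dihedral-only boosts);
* PMF grids and tables: TSV;
* run configuration: flat YAML mapping.

Frames are 0-based, residues 1-based; energies kcal/mol, distances
Angstrom, angles degrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biotite.structure.io.pdb as pdb

from . import __version__
from .amd import BoostLog, FrameWeights, PMFGrid, compute_weights, reweight_histogram
from .constants import DEFAULT_TEMPERATURE
from .convergence import kld_timeseries
from .dihedrals import DihedralSeries, compute_dihedrals, region_occupancy
from .hbonds import detect_hbonds, end_to_end
from .pca import cluster_timeline, cpca, density_cluster, dpca, fel
from .synthetic import (
    SamplerConfig,
    build_toy_chain,
    dihedral_boost,
    double_well,
    helix_spec,
    sample_biased,
)
from .trajectory import TrajectorySet

logger = logging.getLogger("amdreweigh")


# --- trajectory I/O ---

def write_trajectory(traj: TrajectorySet, path) -> None:
    """Write a multi-model PDB."""
    f = pdb.PDBFile()
    pdb.set_structure(f, traj.to_atom_array_stack())
    f.write(str(path))


def read_trajectory(path) -> TrajectorySet:
    """Read a multi-model PDB (consistent atoms across models required)."""
    f = pdb.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(f)
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"inconsistent models in {path}: {exc}") from exc
    return TrajectorySet.from_atom_array_stack(stack)


# --- tabular I/O ---

def write_dihedral_series(series: DihedralSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def read_dihedral_series(path) -> DihedralSeries:
    return DihedralSeries.from_frame(pd.read_csv(path, sep="\t"))


def write_boost_log(log: BoostLog, path) -> None:
    pd.DataFrame(
        {"frame": log.frame_index, "dV_dihed": log.dv_dihed, "dV_total": log.dv_total}
    ).to_csv(path, sep="\t", index=False)


def read_boost_log(path, mode: str = "iamd3_dual") -> BoostLog:
    """Read a boost-log TSV; a missing dV_total column is accepted for
    dihedral-only boosts.  Negative entries are rejected with the
    offending line number."""
    df = pd.read_csv(path, sep="\t")
    if "dV_dihed" not in df.columns:
        raise ValueError(f"{path}: missing required column 'dV_dihed'")
    dv_dihed = df["dV_dihed"].to_numpy(dtype=float)
    if "dV_total" in df.columns:
        dv_total = df["dV_total"].to_numpy(dtype=float)
    else:
        if mode != "iamd2_dihedral":
            raise ValueError(
                f"{path}: no 'dV_total' column; only mode iamd2_dihedral can omit it"
            )
        dv_total = np.zeros_like(dv_dihed)
    for name, arr in (("dV_dihed", dv_dihed), ("dV_total", dv_total)):
        bad = np.flatnonzero(arr < 0)
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: negative {name} on line {bad[0] + 2}")
    return BoostLog(dv_dihed, dv_total, mode=mode)


def write_pmf(grid: PMFGrid, path) -> None:
    """PMF grid as TSV (bin centers + probability + PMF, NaN for empties)."""
    centers = grid.centers
    if grid.ndim == 1:
        df = pd.DataFrame(
            {"center": centers[0], "prob": grid.prob, "pmf": grid.pmf}
        )
    else:
        c0, c1 = np.meshgrid(centers[0], centers[1], indexing="ij")
        names = grid.axis_names or ("q1", "q2")
        df = pd.DataFrame(
            {
                names[0]: c0.ravel(),
                names[1]: c1.ravel(),
                "prob": grid.prob.ravel(),
                "pmf": grid.pmf.ravel(),
            }
        )
    df.to_csv(path, sep="\t", index=False)


# --- run configuration ---

@dataclass
class RunConfig:
    """Flat, serialisable configuration for a full pipeline run."""

    seed: int = 1
    temperature: float = DEFAULT_TEMPERATURE
    estimator: str = "maclaurin"
    maclaurin_order: int = 10
    bins_2d: int = 72
    bins_1d: int = 50
    cluster_components: int = 3
    cluster_bins: int = 50
    cluster_threshold: float = 0.1
    kld_cutoff: float = 0.025
    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    n_steps: int = 200_000
    n_replicas: int = 2
    boost_e: float = 1.0
    boost_alpha: float = 4.0
    toy_n_res: int = 12
    toy_n_frames: int = 50

    def validate(self) -> None:
        if not 0 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must lie in (0, 1]")
        if self.kld_cutoff <= 0:
            raise ValueError("kld_cutoff must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.estimator not in ("exponential", "maclaurin", "cumulant2"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.hbond_distance_cutoff <= 0 or not 0 < self.hbond_angle_cutoff <= 180:
            raise ValueError("H-bond cutoffs out of range")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def pipeline_run(config: RunConfig, out_dir) -> dict:
    """Execute the full synthetic-input pipeline into a run directory.

    simulate -> reweight -> dPCA -> FEL -> cluster -> KLD -> H-bond ->
    end-to-end; every stage logs its parameters and writes TSV outputs.
    Re-running with the same config is bit-identical for the TSV outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": asdict(config), "version": __version__}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    logger.info("simulate: n_steps=%d seed=%d boost E=%.3g alpha=%.3g",
                config.n_steps, config.seed, config.boost_e, config.boost_alpha)
    potential = double_well()
    boost = dihedral_boost(config.boost_e, config.boost_alpha)
    series, log = sample_biased(
        potential,
        SamplerConfig(n_steps=config.n_steps, seed=config.seed,
                      temperature=config.temperature, boost=boost),
    )
    write_dihedral_series(series, out / "dihedrals.tsv")
    write_boost_log(log, out / "amd_log.tsv")

    logger.info("reweight: estimator=%s order=%d", config.estimator, config.maclaurin_order)
    weights = compute_weights(log, config.temperature, config.estimator,
                              config.maclaurin_order)
    phi, psi = series.residue(1)
    pmf = reweight_histogram(
        np.column_stack([phi, psi]), weights, bins=config.bins_2d,
        hist_range=[[-180, 180], [-180, 180]],
        temperature=config.temperature, axis_names=("phi", "psi"),
    )
    write_pmf(pmf, out / "pmf_phi_psi.tsv")

    logger.info("toy chain: n_res=%d n_frames=%d", config.toy_n_res, config.toy_n_frames)
    spec = helix_spec(config.toy_n_res, n_frames=config.toy_n_frames,
                      phi=-60.0, psi=-38.0, jitter=10.0, seed=config.seed)
    traj = build_toy_chain(spec)
    toy_series = compute_dihedrals(traj)
    uw = FrameWeights.uniform(traj.n_frames, temperature=config.temperature)

    logger.info("dpca + fel + cluster: bins=%d threshold=%.3g",
                config.cluster_bins, config.cluster_threshold)
    model = dpca(toy_series)
    pd.DataFrame(
        {"eigenvalue": model.eigenvalues, "variance_fraction": model.variance_fractions}
    ).to_csv(out / "dpca_eigen.tsv", sep="\t", index=False)
    landscape = fel(model, uw, bins=config.bins_2d, temperature=config.temperature)
    write_pmf(landscape, out / "fel_pc1_pc2.tsv")
    n_comp = min(config.cluster_components, model.projections.shape[1])
    assign = density_cluster(model, n_components=n_comp,
                             bins=config.cluster_bins,
                             threshold=config.cluster_threshold)
    pd.DataFrame(
        {
            "cluster": np.arange(1, assign.n_clusters + 1),
            "occupancy": assign.occupancies,
            "representative_frame": assign.representative_frames,
        }
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    times, labels, trans = cluster_timeline(assign, np.arange(traj.n_frames, dtype=float))
    pd.DataFrame({"time": times, "cluster": labels}).to_csv(
        out / "cluster_timeline.tsv", sep="\t", index=False
    )

    logger.info("kld: %d replicas, cutoff=%.3g", config.n_replicas, config.kld_cutoff)
    replicas = [
        sample_biased(
            single_basin_for(potential),
            SamplerConfig(n_steps=max(config.n_steps // 4, 2000),
                          seed=config.seed + 100 + k,
                          temperature=config.temperature,
                          start=potential.centers[0]),
        )[0].phi[:, 0]
        for k in range(config.n_replicas)
    ]
    klds = kld_timeseries(replicas, cutoff=config.kld_cutoff)
    klds.to_frame().to_csv(out / "kld.tsv", sep="\t", index=False)

    logger.info("hbond: dist<=%.2f angle>=%.1f",
                config.hbond_distance_cutoff, config.hbond_angle_cutoff)
    _, hb_table = detect_hbonds(traj, config.hbond_distance_cutoff,
                                config.hbond_angle_cutoff)
    hb_table.to_csv(out / "hbonds.tsv", sep="\t", index=False)
    occ = region_occupancy(toy_series)
    occ.to_csv(out / "region_occupancy.tsv", sep="\t")

    distances, e2e_pmf = end_to_end(traj, uw, bins=config.bins_1d,
                                    temperature=config.temperature)
    write_pmf(e2e_pmf, out / "end_to_end_pmf.tsv")
    pd.DataFrame({"frame": np.arange(distances.size), "distance": distances}).to_csv(
        out / "end_to_end.tsv", sep="\t", index=False
    )
    return {
        "pmf": pmf,
        "pc_model": model,
        "clusters": assign,
        "kld": klds,
        "hbonds": hb_table,
        "end_to_end": distances,
        "out_dir": out,
    }


def single_basin_for(potential):
    """Deepest basin of a potential as a standalone single-well surface."""
    from .synthetic import ModelPotential

    k = int(np.argmax(potential.depths))
    return ModelPotential(
        "gaussian_basins",
        (potential.centers[k],),
        (potential.depths[k],),
        (potential.widths[k],),
    )
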