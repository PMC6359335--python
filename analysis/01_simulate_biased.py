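#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces (a) a boosted Metropolis run on the double-well dihedral
potential with its per-frame boost log, (b) two same-basin and two
disjoint-basin replica runs for the convergence analysis, and (c) a toy
helical peptide trajectory for the structure-based stages.  Everything
downstream reads these files from results/inputs/.
"""

from pathlib import Path

import numpy as np

from amdreweigh import (
    SamplerConfig,
    build_toy_chain,
    dihedral_boost,
    double_well,
    helix_spec,
    make_replicas,
    sample_biased,
    single_basin,
    write_boost_log,
    write_dihedral_series,
    write_trajectory,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    well = double_well()  # helical + extended basins, ~6 kcal/mol barrier
    series, log = sample_biased(
        well,
        SamplerConfig(n_steps=500_000, seed=SEED, boost=dihedral_boost(1.0, 4.0)),
    )
    write_dihedral_series(series, OUT / "biased_dihedrals.tsv")
    write_boost_log(log, OUT / "amd_log.tsv")
    print(f"boosted run: {series.n_frames} frames, "
          f"mean boost {log.dv.mean():.2f} kcal/mol, max {log.dv.max():.2f}")

    same = make_replicas(single_basin(depth=6.0, width=25.0), 2,
                         seeds=[SEED, SEED + 1], overlap_mode="same_basin",
                         n_steps=150_000, record_stride=5)
    for k, rep in enumerate(same, 1):
        write_dihedral_series(rep, OUT / f"replica_same_{k}.tsv")
    apart = make_replicas(double_well(depths=(10.0, 10.0), width=30.0), 2,
                          seeds=[SEED + 2, SEED + 3],
                          overlap_mode="disjoint_basins", n_steps=30_000)
    for k, rep in enumerate(apart, 1):
        write_dihedral_series(rep, OUT / f"replica_disjoint_{k}.tsv")
    print(f"replicas: 2 same-basin ({same[0].n_frames} frames each), "
          f"2 disjoint-basin ({apart[0].n_frames} frames each)")

    helix = build_toy_chain(
        helix_spec(12, n_frames=60, phi=-60.0, psi=-38.0, jitter=10.0, seed=SEED)
    )
    write_trajectory(helix, OUT / "toy_helix.pdb")
    print(f"toy helix: {helix.n_frames} frames x {helix.n_atoms} atoms "
          f"({len(helix.residue_ids)} residues)")


if __name__ == "__main__":
    main()
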