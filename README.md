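# amdreweigh

Reconstruction and analysis of canonical free-energy surfaces from
**accelerated molecular dynamics (aMD)** style biased trajectories, aimed
at peptide-folding studies of the kind used to characterise peptaibols
(short fungal peptides with acetylated N-termini, C-terminal amino
alcohols and helix-promoting Aib/d-Iva residues).

aMD adds a non-negative boost to the potential whenever the instantaneous
energy `V` falls below a threshold `E`,

```
dV(V) = (E - V)^2 / (alpha + E - V)    for V < E,  else 0
E_dihed = V_avg_dihed + a1 * N_res     alpha_dihed = a2 * N_res / 5
E_total = V_avg_total + b1 * N_atoms   alpha_total = b2 * N_atoms
```

which flattens barriers and accelerates rare transitions.  The biased
ensemble is reweighted back to the canonical one with the per-frame
Boltzmann factor `exp(dV / kBT)` — evaluated exactly, by a truncated
Maclaurin series (default: 10th order), or by a bin-wise second-order
cumulant expansion — and binned into potentials of mean force
`mu(q1, q2) = -kBT ln P(q1, q2)`.

On top of the reweighting core the package provides:

* **dihedral extraction and Ramachandran classification** — IUPAC phi/psi
  per residue, nearest-center region labels (alpha, beta, PII, gamma,
  gamma', zeta, with the delta/delta' alpha–beta bridge band);
* **dihedral PCA** (on the periodicity-safe sin/cos transform) and
  **Cartesian PCA** (two-pass Kabsch superposition), reweighted
  free-energy landscapes on PC1/PC2, and density-peak clustering with
  occupancy timelines;
* **convergence assessment** — Gaussian-KDE histograms of PC projections
  and the time-dependent Kullback–Leibler divergence
  `KLD(t) = sum_i P(t,i) ln(P(t,i)/Q(t,i))` between replicas, with the
  0.025 convergence cutoff;
* **structural statistics** — backbone N–H···O=C hydrogen bonds with
  turn-type classes (i+2 gamma, i+3 3_10, i+4 alpha) and end-to-end
  distance PMFs;
* a **synthetic module** generating ground-truth-known inputs: Metropolis
  samplers on analytic periodic potentials (optionally boosted, with
  per-frame boost logs), toy peptide backbones built from (phi, psi)
  series, and multi-replica runs with controllable overlap.

## Worked example

```python
import numpy as np
from amdreweigh import (SamplerConfig, compute_weights, dihedral_boost,
                        double_well, reweight_histogram, sample_biased)

well = double_well()                       # two basins, ~6 kcal/mol barrier
series, log = sample_biased(
    well, SamplerConfig(n_steps=500_000, seed=1, boost=dihedral_boost(1.0, 4.0)))
weights = compute_weights(log)             # Maclaurin-10 by default
grid = reweight_histogram(
    np.column_stack([series.phi[:, 0], series.psi[:, 0]]), weights,
    bins=72, hist_range=[[-180, 180], [-180, 180]])
analytic = well.analytic_pmf(grid.centers[0], grid.centers[1])
sel = grid.mask & (analytic < 4.0)
print(f"mean |PMF error| = {np.mean(np.abs(grid.pmf[sel] - analytic[sel])):.3f}")
```

prints

```
mean |PMF error| = 0.109
```

i.e. the Maclaurin-10 reweighted surface reproduces the analytic
double-well PMF to ~0.1 kcal/mol over all bins below 4 kcal/mol (the
exact exponential estimator reaches ~0.04 kcal/mol on the same run).

The `analysis/` directory holds the same workflow as numbered narrative
scripts (`01_simulate_biased.py` … `06_structure_metrics.py`); each
writes its tables under `results/` and prints what it found.  A thin
umbrella CLI exposes the stages as `amdreweigh simulate | reweight |
dpca | cpca | fel | cluster | kld | hbond | endtoend | pipeline`.

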