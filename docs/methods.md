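# Methods

## Scope and model

The package implements the analysis side of an accelerated-MD (aMD)
peptide-folding study: given a biased trajectory and its per-frame boost
log, recover canonical potentials of mean force and derive conformational
statistics from them.  It does not run molecular dynamics.  All energies
are kcal/mol, distances Angstrom, angles degrees, temperatures Kelvin;
`kB = 0.0019872041 kcal mol^-1 K^-1` and the default temperature is
300 K (`kBT = 0.59616 kcal/mol`).

### Boost model

The boost is the standard single-threshold form
`dV(V) = (E - V)^2 / (alpha + E - V)` for `V < E` and zero otherwise —
non-negative, continuous at `V = E`, monotonically decreasing in `V`.
Threshold and softness derive from per-system coefficients:
`E_dihed = V_avg_dihed + a1 N_res`, `alpha_dihed = a2 N_res / 5` for the
torsion channel and `E_total = V_avg_total + b1 N_atoms`,
`alpha_total = b2 N_atoms` for the total-potential channel.  Three modes
are supported: total-only (`iamd1_total`), dihedral-only
(`iamd2_dihedral`) and dual (`iamd3_dual`).  The effective per-frame
bias used in reweighting is the sum of the active channels; a mode whose
active channel has a zero coefficient is rejected (its `alpha` would
vanish).

### Reweighting estimators

Frame weights are Boltzmann factors of the boost, `w = exp(dV/kBT)`.
Three estimators are implemented:

* `exponential` — the exact factor; statistically noisy when boosts are
  large because a few high-`dV` frames dominate;
* `maclaurin` (default, order 10) — the truncated series
  `sum_{j<=k} (dV/kBT)^j / j!`; monotonically approaches the exponential
  as `k` grows and is within 1e-6 relative for `dV <= kBT` at `k = 10`;
* `cumulant2` — applied bin-wise during histogramming: each bin's biased
  probability is multiplied by `exp(beta <dV> + beta^2 var(dV)/2)` using
  the boost moments of the frames in that bin.  Accurate when the
  per-bin boost distribution is near-Gaussian; the third-order term is
  deliberately not implemented.

PMF grids normalise probability over populated bins, anchor the minimum
at zero and mask empty bins (NaN) rather than assigning them zero free
energy.  Reweighting is invariant to scaling all weights by a positive
constant.

## Synthetic study systems

Production-scale systems (a solvated 18-mer peptaibol, microsecond
trajectories) cannot be regenerated at desk scale, so every stage is
exercised on synthetic inputs whose ground truth is known analytically:

* **Model potentials** — sums of inverted Gaussian basins on a
  360-degree-periodic 2D torus.  The default double well places basins
  at the right-handed-helical (-63, -43) and extended (-157, 161)
  Ramachandran centers with depths 6 and 4 kcal/mol and width 30 deg,
  giving a ~6 kcal/mol barrier that brackets the few-kcal/mol barriers
  typical of short-peptide landscapes.
* **Sampler** — Metropolis Monte Carlo with Gaussian angular proposals
  (default 10 deg) and periodic wrapping, targeting
  `exp(-(V + dV)/kBT)`.  MD would realise the same stationary
  distribution; the reweighting machinery only needs the distribution,
  not dynamics.  The seed fixes runs bit-for-bit.  The standard boosted
  condition uses `E = 1.0`, `alpha = 4.0` on the default double well:
  boosts reach ~4.5 kcal/mol in the deep basin (`dV/kBT` up to ~7.5),
  large enough that the exponential/Maclaurin estimators genuinely
  differ, while the effective barrier drops to ~1.7 kcal/mol and the run
  mixes well within 5e5 steps.
* **Toy backbones** — NeRF chain extension with ideal geometry
  (N–CA 1.458, CA–C 1.525, C–N 1.329 A; angles 111.2/116.2/121.7 deg;
  omega fixed at 180; carbonyl O and amide H placed in the peptide
  plane, H anti to O).  Recomputing phi/psi from built coordinates
  reproduces the input series to 1e-6 deg.  Residue 1 carries no amide H
  and the chain no terminal extras.
* **Replicas** — `same_basin` starts all replicas in the deepest well;
  `disjoint_basins` starts them in different wells of a high-barrier
  (>= 8 kcal/mol) potential so they cannot mix at the given length.

What the generator does *not* emulate: solvent, force-field detail,
kinetics, side chains, and the thermostat/barostat machinery of real MD.
Passing tests therefore demonstrate the correctness of the analysis
operators on ensembles with the right statistical structure, not the
behaviour of any particular peptide.

## Analysis stages and numerical choices

* **Dihedrals** — IUPAC phi = C(i-1)–N–CA–C, psi = N–CA–C–N(i+1),
  wrapped to [-180, 180); chain-end angles are NaN, never zero-filled.
  Degenerate (collinear) quadruples raise.
* **Ramachandran classification** — nearest tabulated center under
  periodic Euclidean distance in (phi, psi): alpha_R (-63, -43),
  alpha_L (+63, +43) (mirror convention; no left-handed center is
  tabulated in the source nomenclature), beta (-157.2, 161.9),
  PII (-65, 145), gamma (80, -80), gamma' (-80, 80), zeta (-130, 80).
  Points nearest the alpha center whose distance to the beta center is
  within 25 deg of the alpha distance are assigned to the delta
  (alpha-beta bridge) band, delta' for the mirror.  The band width is a
  design choice — the bridge region is described only verbally in the
  nomenclature — and is exposed as a parameter.  The classification is
  total and invariant under 360-degree shifts; ties break toward the
  earlier tabulated center.
* **dPCA** — PCA of (cos phi, sin phi, cos psi, sin psi) per residue;
  raw-angle PCA is wrong under periodicity.  Constant series are
  rejected (zero covariance).
* **cPCA** — two-pass superposition (Kabsch fit to the first frame, then
  to the average structure) before diagonalising the coordinate
  covariance; default selection is the backbone heavy atoms.  Purely
  rigid-body motion yields numerically zero eigenvalues, reported as
  zeros with zero variance fractions rather than an error.
* **FEL** — reweighted 2D histogram over PC1/PC2 through the same PMF
  pipeline; 72 bins per axis for dihedral spaces (5-degree bins),
  50 bins for 1D distances.
* **Density clustering** — histogram the top k PC projections (default
  3 components, 50 bins/axis); bins with density >= threshold x max
  (default 0.1) form superlevel islands; each connected island is one
  cluster with its densest bin as peak.  Frames inside an island belong
  to it; frames within two grid cells adopt the nearest island; the rest
  stay unassigned (cluster 0).  Occupancies use all frames in the
  denominator.  Connected components rather than raw local maxima make
  the peak count robust to histogram shot noise.
* **KLD convergence** — Gaussian-KDE densities (Silverman bandwidth per
  sample prefix) on a shared 512-point grid spanning the union range
  padded by three bandwidths; divergence summed over grid points
  populated by both densities after renormalising on that joint support
  (mirroring the exclusion of unpopulated bins).  If the supports are
  disjoint the pairwise divergence is undefined and the time series
  records +inf.  A pair is converged at the first horizon after which
  KLD stays below the cutoff (default 0.025, a divergence value, not a
  slope — a slope threshold would carry arbitrary time units) through
  the end of the data; later excursions clear the flag.  Evaluation
  horizons default to every 5% of the shortest replica.
* **H-bonds** — backbone N–H···O=C only; present when the O···N
  heavy-atom distance is <= 3.0 A and the N–H···O angle at H is
  >= 135 deg (cutoffs consistent with typical helical bond geometry,
  2.78–2.91 A and 146–163 deg averages).  The acceptor is the carbonyl
  O of its residue.  Donors without an amide H (proline, chain start)
  are skipped.  Self and adjacent (donor = acceptor + 1) pairs are
  excluded as covalently constrained.  Offsets 2/3/4 map to
  gamma/3_10/alpha turn classes.  Averages are over present frames
  only.  Enlarging the distance cutoff or relaxing the angle cutoff can
  only grow fractions.
* **End-to-end distance** — first residue N to the last residue's
  C-terminal heavy atom (OXT when present, else C), with a reweighted
  1D PMF.

## Convergence-test conditions

The same-basin convergence analogue samples a single 6 kcal/mol-deep,
25-degree-wide well for 150k steps recording every 5th step: thinning
decorrelates the chain and the depth keeps the near-uniform background
of the bounded well below ~1% occupancy, so two independent replicas
reach terminal KLD ~0.003, comfortably below the 0.025 cutoff.  The
mid-run basin-switch signature (early dip, later rise above the cutoff)
is constructed by concatenating a same-basin prefix with a
disjoint-basin continuation.

## Known limitations

* The sampler is Monte Carlo: timelines and transition counts measure
  sampler dynamics, not physical kinetics.
* The cumulant expansion stops at second order; strongly non-Gaussian
  per-bin boost distributions will bias it.
* Clustering operates on fixed-grid histograms; very small clusters
  (below a grid cell's population noise) merge into the background.
* The toy backbone uses fixed ideal bond lengths/angles, so absolute
  H-bond geometries differ slightly from relaxed structures; only
  relative/statistical properties are meaningful.
* The dual-boost mode sums both channels into the reweighting exponent;
  channel-resolved reweighting is not attempted.
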