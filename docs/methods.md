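# Methods

`voxconn` analyses resting-state functional connectivity *within* a single
cortical region at voxel resolution: every grey-matter voxel of an ROI is a
network node, edges are supra-threshold zero-lag correlations between voxel
time series, and the questions are about the architecture of that graph —
how locally clustered it is, how short its paths are, and whether an
intervention (e.g. transcranial direct current stimulation over primary
motor cortex) reorganizes it.

## Analysis model

**Preprocessing.** Raw ROI time series (voxels × volumes) are cleaned by:
discarding the first two volumes (magnetization equilibrium); OLS
regression of nine nuisance signals (six rigid-body motion parameters,
mean WM, mean CSF, global signal) plus an intercept; per-voxel AR(1)
prewhitening (Yule–Walker); and a zero-phase (forward–backward) 4th-order
Butterworth band-pass at 0.01–0.09 Hz. Motion QC excludes datasets whose
per-trace rms exceeds 1 mm or 1°. The order
regress → prewhiten → band-pass is the default; the alternative
prewhiten-first order remains available because the literature does not fix
it, and the applied order is always recorded in the provenance.

**Graphs.** The synchronization matrix M holds all-pairs Pearson
correlations. An undirected simple graph keeps edges where r > T strictly;
negative correlations never form edges. The adaptive threshold scan raises
T from 0.1 in steps of 0.002 until the giant component holds less than 95 %
of nodes; the last admissible grid point is the dataset's T_max, and group
analyses use the minimum T_max over all datasets so that every graph is
thresholded identically. Graphs are then restricted to their largest
component.

**Metrics and nulls.** Nodal degree K_i, Watts–Strogatz local clustering
C_i (0 for degree < 2) and mean shortest-path length L_i (BFS distances);
global K, C, L are unweighted means over the largest component. Null
references come either from the analytic formulas C_rand = K/N,
L_rand = ln N / ln K, or (the default for maps) from an ensemble of
Maslov–Sneppen double-edge-swap randomizations (10·|E| attempted swaps per
replicate, degree sequence preserved exactly; fragmented replicates are
restricted to their largest component, mirroring the treatment of the
empirical graphs). Small-worldness is σ = γ/λ with γ = C/C_rand and
λ = L/L_rand.

**Maps.** Nodal metrics become per-voxel maps: K_i scaled by the
individual map maximum; C_i divided by the dataset's C_rand; L_i inverted
as L_rand/L_i so that larger always means better integrated. Maps are
smoothed with a mask-restricted Gaussian kernel (weights renormalized over
in-mask, non-missing voxels; 6 mm FWHM default). Hubs are the top 15 % of
the subject-averaged baseline L_rand/L_i map (ceiling count, ties
included).

**Statistics.** Global metrics: two-tailed paired t per session and
threshold. Maps: a voxelwise two-way repeated-measures ANOVA
(stimulation × time) whose interaction F map gates post-hoc paired t maps;
cluster correction thresholds the map at parametric p < 0.05, groups
supra-threshold voxels by 26-connectivity on the voxel lattice, and
compares observed cluster extents against the permutation null of the
maximum extent (sign-flipping of subject difference maps for t maps;
within-subject session-label permutation for the interaction; 5000
permutations by default), with corrected
p = (1 + #{perm max ≥ size}) / (1 + n_perm). Positive and negative t
clusters are formed separately. Baseline dependence regresses each
subject's cluster-mean (after − before) change on its cluster-mean
baseline value by OLS.

Differences from a surface-based original of this workflow: smoothing,
cluster formation and cluster sizes (voxels, mm³) live on the voxel
lattice, not a reconstructed cortical surface; adjacency is configurable
(6/18/26).

## The synthetic data generator

The generator exists so that every stage can be validated against ground
truth; it emulates the statistical structure the pipeline assumes rather
than the biophysics of BOLD.

* **Band-limited latents.** A session of T volumes at TR seconds carries at
  most `band_capacity(T, TR)` (≈ 50 for 175 volumes at 1.8 s) independent
  band-limited signals — the dimension of the in-band DFT subspace. Latents
  are a random rotation of that exact Fourier basis: exactly orthonormal,
  exactly in-band, spectrally flat. This both stabilizes graph density
  across sessions and makes the model covariance of any mixture exact.
* **Spatial structure.** Mixing weights decay exponentially with lattice
  distance from randomly seeded community centres (length scale 0.7 voxels,
  one centre per ~5 voxels, capped at the band capacity); rows are
  normalized so each voxel carries the same signal variance. With the
  default in-band signal/noise sd ratio of 1.0 this yields
  nearest-neighbour correlations near 0.45, per-dataset T_max around
  0.35–0.45, mean degree ≈ 20 at the group threshold and γ ≈ 2–3 — a
  sparse small-world regime. (At the originally considered length scale of
  2 voxels the correlation structure is so diffuse that thresholded graphs
  are near-complete and no small-world regime exists; the shorter length
  scale is a calibration requirement, not a tuning afterthought.)
* **Noise and nuisance.** AR(1) voxel noise (φ = 0.3) gives the
  prewhitening stage something to remove. Nuisance contamination couples
  every voxel to a slow drift/physiological "global" trace and weakly to
  motion (smooth random walks, rms 0.2 mm/° by default, with a switch to
  violate QC) and WM/CSF traces. Per-subject *architecture* (community
  centres, weights, nuisance couplings, shortcut partners) is drawn from a
  separate seed stream so that repeated sessions of one subject share a
  stable functional architecture and differ only in noise — without this,
  paired before/after contrasts are hopelessly noisy.
* **Planted effects** re-mix the existing latents (the band cannot carry
  new ones) with per-voxel signal power preserved exactly, so an effect
  cannot leak into global graph density through the data-adaptive
  prewhitening filter. `local_coupling` pulls each target voxel's profile
  toward its local within-target mean *minus* a dose
  (`boundary_decoupling`, default 1.8) of the surrounding non-target
  profiles: synchronization is redistributed from the target's boundary
  into the target, raising local clustering while the expected connection
  count stays roughly flat — the dissociation this class of experiment
  reports. `long_range` moves both ends of target↔distal-partner links
  toward each other, creating supra-threshold functional shortcuts. The
  mixing fraction is solved from the covariance model so the mean pairwise
  correlation over the affected pairs rises by the requested δ (within-
  target mean for local coupling, link mean for shortcuts), saturating at
  the architecture's feasible bound for weakly coupled subjects. The
  default shortcut δ is 0.25 rather than 0.15 because link correlations
  start near zero and must clear the ≈0.35 group threshold to create any
  shortcut edge at all.
* **Study designs** are fully crossed (subjects × {anodal, cathodal,
  sham} × {before, after}; 14 × 3 × 2 = 84 datasets by default), with
  effects only in non-sham "after" cells. Per-subject heterogeneity scales
  the baseline coupling (log-normal, sd 0.2) and, optionally, the effect
  size with a planted latent correlation ρ to the baseline — the substrate
  for baseline-dependence analyses.

**What the generator does not emulate:** hemodynamic response functions,
neural-mass dynamics, scanner artefacts beyond slow drift, actual head
motion (motion exists only as regressor traces), spatial inhomogeneity of
tSNR, and non-stationarity. Passing tests therefore show that the
*pipeline* behaves correctly on data with the assumed covariance
structure; they cannot certify performance on real BOLD.

## Numerical choices and edge cases

* Threshold comparisons are strict (r > T); the percolation criterion is
  ≥ 0.95 of nodes; component ties break toward the lowest node index.
* C_i of degree-0/1 nodes is 0; L is only defined on the largest
  component (callers must restrict first, enforced with an error).
* Rank-deficient nuisance designs drop collinear columns with a warning;
  constant voxel series prewhiten to zeros with a warning; zero-variance
  paired differences give t = 0/p = 1 if all-zero, NaN with a warning
  otherwise; an interaction with zero interaction variance reports F = 0.
* Smoothing truncates the Gaussian at 3.5 σ and renormalizes over valid
  in-mask voxels, so constants are preserved and missing voxels neither
  receive nor contribute weight.
* All randomness flows from numpy `SeedSequence` fan-out: one master seed
  determines study simulation, every null ensemble and every permutation
  test; reports are byte-identical across reruns.

## Reduced-scale validation conditions

The simulation studies used by the validation suite and
`scripts/acceptance.py` run at a deliberately reduced scale chosen once:
200-voxel ROIs (40-voxel planted targets), 14 subjects, 10–20 null
replicates per dataset, 1000 permutations, and 4 mm FWHM smoothing — on a
~27 × 24 × 9 mm miniature lattice, 4 mm is proportionally closer to what
6 mm does on a full-size cortical patch. Effect-recovery rates are
estimated from 10 study replicates per effect kind, type-I rates from 100
null studies (map level) and 500 simulated nulls (scalar level), and
baseline-dependence recovery from 100 replicates.

Two known limitations surface there. First, in a binary thresholded graph
the degree, clustering and path-length maps are mechanically coupled: any
planted correlation change moves all three, and the degree map is the
least noisy of them, so the clean "C up, K silent" / "L up, K silent"
dissociation is only partially reproducible at δ ≈ 0.15–0.25 and n = 14 —
the boundary-decoupled redistribution effect gets close, but a minority of
replicates still show a corrected degree or off-target cluster. Second,
the baseline-dependence R² recovered from measured maps is attenuated by
graph-estimation noise (two ~56-effective-dof sessions per subject) well
below the planted ρ²; the regression also inherits a small
regression-to-the-mean artefact because the baseline map appears on both
sides of the regression. Both are properties of the analysis design
itself, not implementation defects, and both are measured rather than
hidden by the test suite.
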