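# voxconn

Voxel-level graph analysis of resting-state functional connectivity within
a single cortical region — for neuroimaging researchers who want to ask
whether an intervention (e.g. transcranial direct current stimulation over
primary motor cortex) reorganizes the *intrinsic* functional architecture
of an ROI, not just its activity level.

Every grey-matter voxel of the ROI is a network node. From cleaned BOLD
time series the package builds the N×N zero-lag Pearson synchronization
matrix M, thresholds it into an undirected graph G (edge iff r > T), and
characterizes the architecture with:

* **K_i** — nodal connectivity degree (number of supra-threshold
  connections);
* **C_i** — nodal clustering coefficient (fraction of a voxel's neighbour
  pairs that are themselves connected);
* **L_i** — nodal characteristic path length (mean shortest graph distance
  to all other voxels);
* **small-worldness** σ = γ/λ, with γ = C/C_rand and λ = L/L_rand measured
  against degree-preserving rewired null graphs (1000 by default);
  σ ≫ 1 means the region is simultaneously segregated and integrated.

The analysis threshold is found by a percolation scan (raise T from 0.1 in
steps of 0.002 until the giant component drops below 95 % of voxels; the
group uses the minimum per-dataset T_max). Nodal metrics become normalized
per-voxel maps (K/max, C_i/C_rand, L_rand/L_i), which enter a voxelwise
repeated-measures ANOVA (stimulation × time) with Monte-Carlo
cluster-extent correction by permutation, post-hoc paired-t contrasts,
baseline-dependence regression, and hub mapping (top 15 % of baseline
L_rand/L_i).

Because suitable raw data are rarely shareable, the package ships a
first-class synthetic BOLD generator (`voxconn.simulate`) that produces
band-limited, spatially structured, nuisance-contaminated voxel time
series with *plantable* connectivity effects (a local-coupling increase or
long-range shortcuts, confined to a known target subregion), so the entire
pipeline can be validated against ground truth.

## Worked example

```bash
python examples/02_graphs_and_small_world.py
```

prints (exact numbers, seed 3):

```
synchronization matrix: 200 x 200
percolation scan: T_max = 0.442 (173 grid points)
graph at T_max: 193 nodes, 535 edges, mean degree 5.5
C = 0.314 vs C_rand = 0.040  -> gamma = 7.76
L = 4.198 vs L_rand = 3.226  -> lambda = 1.30
small-worldness sigma = gamma/lambda = 5.96
```

i.e. at its own percolation threshold this synthetic ROI keeps 96 % of
voxels in one component, is ~8× more clustered than degree-matched random
graphs while its paths are only 30 % longer — a strongly small-world
architecture. `examples/01_simulate_and_preprocess.py` walks through the
cleaning chain, and `examples/03_full_study_pipeline.py` runs a miniature
before/after stimulation study end to end, recovering a planted
clustering-map effect in the cathodal session and a path-length effect in
the anodal session while the degree map stays silent.

A thin CLI wraps the orchestrator: `voxconn simulate --out dir/ --seed 1`
writes a synthetic study as HDF5; `voxconn run --config cfg.yaml --out
dir/ --seed 1` runs the full pipeline and writes a machine-readable
report.

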