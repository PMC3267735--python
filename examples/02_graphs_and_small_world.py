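"""From time series to a small-world functional graph.

Computes the voxelwise synchronization matrix, scans the percolation
threshold (raise T until <95% of voxels remain in the giant component),
builds the graph at T_max, and compares its clustering and path length
against 100 degree-preserving rewired null graphs.
"""

from voxconn import (correlation_matrix, global_metrics, make_roi,
                     null_ensemble, preprocess_session, restrict_to_largest,
                     scan_tmax, simulate_session, threshold_graph)

roi = make_roi(200, "slab", seed=1)
clean = preprocess_session(*simulate_session(roi, seed=3))
M = correlation_matrix(clean)
print(f"synchronization matrix: {M.n_nodes} x {M.n_nodes}")

scan = scan_tmax(M)          # T = 0.1 upward in steps of 0.002
print(f"percolation scan: T_max = {scan.T_max:.3f} "
      f"({len(scan.T_grid)} grid points)")

G = restrict_to_largest(threshold_graph(M, scan.T_max))
print(f"graph at T_max: {G.n_nodes} nodes, {G.n_edges} edges, "
      f"mean degree {G.degrees().mean():.1f}")

null = null_ensemble(G, n_replicates=100, seed=0)
gm = global_metrics(G, null)
print(f"C = {gm.C:.3f} vs C_rand = {gm.C_rand:.3f}  -> gamma = {gm.gamma:.2f}")
print(f"L = {gm.L:.3f} vs L_rand = {gm.L_rand:.3f}  -> lambda = {gm.lam:.2f}")
print(f"small-worldness sigma = gamma/lambda = {gm.sigma:.2f}")
print("sigma >> 1: locally clustered AND globally integrated, the "
      "small-world regime expected of cortical voxel networks")
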