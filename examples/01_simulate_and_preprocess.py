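"""Simulate one resting-state session and clean it.

Builds a 200-voxel ROI, generates a BOLD-like series with nuisance
contamination, runs the preprocessing chain (discard dummies -> regress 9
nuisance signals -> AR(1) prewhitening -> 0.01-0.09 Hz band-pass) and
prints what each stage did to the data.
"""

import numpy as np

from voxconn import (NuisanceSet, discard_initial_volumes, make_roi,
                     motion_qc, nuisance_regression, preprocess_session,
                     simulate_session)

roi = make_roi(200, "slab", seed=1)
bold, nuisance = simulate_session(roi, seed=3)
print(f"raw series: {bold.n_voxels} voxels x {bold.n_timepoints} volumes, "
      f"TR = {bold.tr_seconds} s")

passed, rms = motion_qc(nuisance.motion)
print(f"motion QC: {'pass' if passed else 'FAIL'} "
      f"(max rms = {rms.max():.3f} mm/deg; limit 1.0)")

clean = preprocess_session(bold, nuisance)
print(f"clean series: {clean.n_timepoints} volumes after discarding dummies "
      f"and one prewhitening lag")
print("steps applied:", " -> ".join(clean.provenance["steps"]))

# nuisance removal: regression residuals are orthogonal to every regressor
# (checked before prewhitening/filtering, which re-weight the spectrum)
trimmed = discard_initial_volumes(bold, 2)
regressed = nuisance_regression(trimmed,
                                NuisanceSet(nuisance.regressors[:, 2:]))
worst = max(abs(np.corrcoef(row, reg)[0, 1])
            for row in regressed.data[:20]
            for reg in nuisance.regressors[:, 2:])
print(f"max |corr(residual, regressor)| over 20 voxels: {worst:.2e}")
# the band-pass keeps only the slow resting-state fluctuations, so
# neighbouring voxels end up sharing most of their remaining variance
r = np.corrcoef(clean.data[:2])[0, 1]
print(f"correlation of two adjacent voxels after cleaning: r = {r:.2f}")
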