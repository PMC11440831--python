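"""Generate a small synthetic abdominal CT cohort and inspect its ground truth.

Each phantom is a 3-D HU volume with a segmented vertebral column, lungs,
pelvis, and muscle/fat compartments; the generator also returns the L3
position and the tissue label map of the L3 axial slice.
"""

import numpy as np

from bodycomp import CohortVariability, PhantomSpec, generate_cohort, LABEL_NAMES

cohort = generate_cohort(3, PhantomSpec.desk(), CohortVariability(), seed=11)

for i, (volume, truth) in enumerate(cohort):
    labels = truth.tissue_labels.labels
    counts = {LABEL_NAMES[c]: int((labels == c).sum()) for c in np.unique(labels)}
    print(f"phantom {i}: shape {volume.voxels.shape}, slice thickness "
          f"{volume.spacing_mm[0]:.1f} mm, L3 at slice {truth.l3_slice_index} "
          f"(z = {truth.l3_z_mm:.1f} mm)")
    print(f"  L3-slice label pixel counts: {counts}")

# Pixel counts scale with the jittered body size; the L3 slice index moves
# with the jittered column position and slice thickness.
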