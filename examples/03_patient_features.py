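"""Compute the 166-entry morphometric profile of one patient tile.

Segments a synthetic tile from detected seeds, computes per-cell
geometry/intensity/texture descriptors, and aggregates them into the
named patient feature vector (area1..t4).
"""

import numpy as np

from histomarkers import features as feat
from histomarkers import segmentation, synthetic
from histomarkers.detection import (DetectionConfig, VotingScale,
                                    detect_seeds)

spec = synthetic.SyntheticImageSpec(width=192, height=192, n_cells=8,
                                    rng_seed=3)
rgb, _, _ = synthetic.synth_cell_image(spec)

config = DetectionConfig(scales=(VotingScale(4, 8), VotingScale(8, 16)))
seeds = detect_seeds(rgb, config)
result = segmentation.segment(rgb, seeds)
mask = result.label_mask
print(f"segmented cells: {mask.max()}")

lab = feat.lab_channels(rgb)
patches = []
for lb in range(1, mask.max() + 1):
    ys, xs = np.nonzero(mask == lb)
    patches.append(lab[ys.min():ys.max() + 1, xs.min():xs.max() + 1, 0])
texton_model = feat.fit_texton_model(patches, k=4, rng_seed=0)

cells = [feat.cell_descriptor(rgb, mask, lb, texton_model, lab=lab)
         for lb in range(1, mask.max() + 1)]
vector = feat.aggregate_patient_vector(cells, patient_id="demo")

print(f"feature entries: {len(vector)}")
print(vector[["area1", "area2", "area3", "cir1", "solidity1",
              "mean1", "entr1", "lbp1", "tfcm1", "csac1", "t1"]]
      .round(3).to_string())
# areaN/cirN/... follow the suffix convention: 1 = across-cell mean,
# 2 = median, 3 = variance, 4-6 = the three frequencies of a 3-bin
# histogram of the per-cell values; texture histograms contribute their
# per-bin moments.
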