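"""Sliding-window prediction mechanics, shown with a stub model.

Variable-length volumes are covered by overlapping z-crops (75% overlap);
each crop's probabilities are blended with a trapezoid weight profile —
full weight on the central slices, a linear taper to nearly zero at the
crop edges — and the ensemble averages fold models' probability maps.
"""

import numpy as np

from hepavol import infer
from hepavol.preprocess import MultiWindowVolume

profile = infer.make_weight_profile(crop_z=32, plateau=16, taper=8)
print("weight profile:", np.round(profile.weights, 3))
print("window starts for a 64-slice volume:", infer.window_starts(64, 32, 0.75))


class StubModel:
    """Emits one fixed class distribution everywhere (no learning involved)."""

    def __init__(self, dist):
        self.dist = np.asarray(dist)

    def __call__(self, crop):
        return np.broadcast_to(self.dist[:, None, None, None],
                               (3,) + crop.shape[1:]).copy()


vol = MultiWindowVolume(np.zeros((3, 64, 16, 16), np.float32), (1.5, 1.5, 5.0))
pv = infer.ensemble_predict(vol, [StubModel([0.7, 0.2, 0.1]),
                                  StubModel([0.5, 0.4, 0.1])], crop_z=32)
print("aggregated class probabilities (should be the 0.6/0.3/0.1 average):",
      np.round(pv.probs[:, 0, 0, 0], 6))
print("max per-voxel deviation from the mean field:",
      float(np.abs(pv.probs - pv.probs[:, :1, :1, :1]).max()))

# The weighted aggregation is conservative: constant model output passes
# through unchanged (seam-free stitching), and the ensemble is the plain
# average of the fold probability maps.
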