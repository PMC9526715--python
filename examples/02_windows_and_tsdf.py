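"""Preprocessing: multi-window HU composite and t-SDF regression targets.

The network input stacks three Hounsfield windows (full 12-bit range,
abdominal soft tissue, liver tissue), each linearly mapped to [−1, 1].
The auxiliary regression target is a per-lobe truncated signed distance
field: +1 deep inside a lobe, −1 far outside, clipped at ±25 mm.
"""

import numpy as np

from hepavol.phantom import PhantomSpec, generate_phantom
from hepavol.preprocess import DEFAULT_WINDOWS, make_composite
from hepavol.tsdf import compute_tsdf

ct, labels = generate_phantom(PhantomSpec(shape=(24, 64, 64), seed=3,
                                          liver_axes_mm=(42, 28, 33)))
comp = make_composite(ct)
liver = labels.labels > 0
for ch, w in enumerate(DEFAULT_WINDOWS):
    inside = comp.channels[ch][liver].mean()
    outside = comp.channels[ch][~liver].mean()
    print(f"window {w.name:22s} (WC {w.center:6.1f}, WW {w.width:6.0f}): "
          f"liver mean {inside:+.2f}, background mean {outside:+.2f}")

ts = compute_tsdf(labels)
for i, name in enumerate(("right lobe", "left lobe")):
    inside = labels.labels == (i + 1)
    print(f"t-SDF {name}: range [{ts.fields[i].min():+.2f}, {ts.fields[i].max():+.2f}], "
          f"sign agrees with labels at "
          f"{100 * ((ts.fields[i] > 0) == inside).mean():.1f}% of voxels")

# The liver window separates parenchyma (+0.75) from background (clipped
# −1); the t-SDF is positive exactly inside each lobe and saturates to ±1
# beyond the 25 mm truncation band.
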