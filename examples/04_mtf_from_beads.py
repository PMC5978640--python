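"""In-plane MTF from the ramp beads used as point sources.

The 0.18 mm beads are effectively point sources at ~0.1 mm pixels; the
Fourier transform of a bead's background-subtracted patch gives MTF(x)
and MTF(y).  The simulated acquisition blurs x more than y (tube travel
direction), so MTF(x) should fall below MTF(y).
"""

import numpy as np

from tomoqa import AcquisitionModel, default_geometry, render
from tomoqa.geometry import bead_positions
from tomoqa.resolution import average_mtf, extract_psf, mtf_from_psf

geometry = default_geometry()
acq = AcquisitionModel(noise_base_sd=0.0, inplane_blur=(0.25, 0.12))
volume = render(geometry, acq)

curves_x, curves_y = [], []
for ramp in geometry.ramps:
    for p in bead_positions(ramp):
        if np.min(np.abs(volume.z_positions - p[2])) > 0.25:
            continue  # only in-focus beads for the headline MTF
        try:
            patch = extract_psf(volume, p)
        except ValueError:
            continue  # neighbour contamination near the ramp fold
        cx, cy = mtf_from_psf(patch)
        curves_x.append(cx)
        curves_y.append(cy)

mx = average_mtf(curves_x)
my = average_mtf(curves_y)
print(f"averaged over {len(curves_x)} beads")
for f in (0.5, 1.0, 2.0, 3.0):
    print(f"f = {f:3.1f} cyc/mm   MTF(x) = {mx.at(f):.3f}   "
          f"MTF(y) = {my.at(f):.3f}")
f50x = np.interp(0.5, mx.modulation[::-1], mx.frequency[::-1])
f50y = np.interp(0.5, my.modulation[::-1], my.frequency[::-1])
print(f"50% modulation: x at {f50x:.2f} cyc/mm, y at {f50y:.2f} cyc/mm")
# With sigma_x > sigma_y the x curve drops faster at every frequency;
# the 50% point quantifies the anisotropy.
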