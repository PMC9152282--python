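"""Traveling front of the scalar bistable equation in a 3D cylinder.

u_t = D lap(u) - u (1-u)(alpha-u) supports a front moving at
sqrt(2 D)(1/2 - alpha).  One random orientation of a 251x2 um cylinder is
simulated at dx=0.25 and the measured front speed is compared with the
plane-wave value.  Takes about a minute.
"""

from voxelrxd import bistable_wave_speed
from voxelrxd.experiments import wave_speed_study

alpha = 0.25
c = bistable_wave_speed(alpha)
errs = wave_speed_study(n_orientations=1, seed=3, alpha=alpha)
print(f"plane-wave speed: {c:.5f} um/ms")
print(f"relative error of the measured speed: {errs[0] * 100:.2f} %")
# Orientation relative to the grid matters: across orientations the error
# stays below ~4% at this resolution, a few percent on average.
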