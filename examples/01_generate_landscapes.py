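"""Generate poor and rich pay-off landscapes and describe their structure.

A landscape merges n single-peak sub-landscapes (Gaussian bumps of width 1
around squared standard-normal heights) by a cell-wise maximum, then
rescales to integers in [0, scale_max].  Poor landscapes (n=32) have a few
isolated pay-off islands; rich ones (n=512) are densely bumpy.
"""

import numpy as np

from ttbsearch import generate_landscape, generate_1d_landscape

rng = np.random.default_rng(1)

for n_peaks in (32, 512):
    ls = generate_landscape((63, 63), n_peaks, rng)
    positive = np.count_nonzero(ls.payoffs)
    print(f"{ls.kind:>5} landscape: n_peaks={n_peaks:3d}  scale_max={ls.scale_max}  "
          f"{positive}/{ls.payoffs.size} cells with pay-off > 0")

line = generate_1d_landscape(32, rng)
print(f"\n1-D landscape (row {line.source_row} of a fresh poor landscape):")
print("  pay-offs:", " ".join(str(v) for v in line.payoffs[0]))
print("\nThe positive-cell count is the footprint of the smoothed peaks: rich")
print("landscapes cover most of the grid, poor ones leave it largely barren.")
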