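"""Invasion phase diagram over essentiality and group size.

Maps which mechanism of dividing labor wins across a grid of
essentiality (eps) and group size (n) at fixed coordination cost, for a
clonal (l=1) and a low-relatedness (l=8) population, and tabulates how
the regions shift.
"""

import numpy as np

from labordiv import phase_grid

eps_axis = np.round(np.arange(0.05, 1.0001, 0.05), 10)
n_axis = np.arange(8, 161, 8)

for l in (1, 8):
    grid = phase_grid(l, theta=0.025, epsilon_axis=eps_axis, n_axis=n_axis)
    print(f"\nl = {l} founders (whole-group relatedness {1/l:.3f}):")
    print(grid.region_counts().to_string())

# Lowering relatedness (l = 1 -> 8) shrinks the coordinated_wins region
# and grows the no_division_of_labor region: with more unrelated
# lineages per group, helping is less favored and the noise of random
# specialization is buffered by the other lineages, so paying for
# coordination is rarely worthwhile.
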