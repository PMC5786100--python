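"""Projection-approximation CCS of a bead chain in helium.

The projection approximation averages the hard-disk shadow of the
molecule over random orientations — cheap, and a useful sanity scale
for the trajectory method.
"""

import numpy as np

from glycoccs import ccs_projection, load_gas

helium = load_gas("He", temperature=300.0)
# a short carbon chain, 2.5 A spacing
coords = np.column_stack([2.5 * np.arange(6), np.zeros(6), np.zeros(6)])
result = ccs_projection(coords, ["C"] * 6, helium,
                        n_orientations=400, n_darts=4000, seed=0)
print(f"projection CCS: {result.omega:.1f} +- {result.standard_error:.1f} A^2 "
      f"({result.n_samples} darts)")

single = ccs_projection(np.zeros((1, 3)), ["C"], helium, seed=0,
                        radii=np.array([2.0]))
print(f"single atom, combined radius 2 A: {single.omega:.2f} A^2 "
      f"(circle area pi*r^2 = {np.pi * 4:.2f})")
# The chain's CCS exceeds one atom's because the orientation-averaged
# shadow grows with every exposed atom.
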