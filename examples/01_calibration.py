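"""Fit the drift-time -> CCS line on polyalanine standards and apply it.

Traveling-wave ion mobility measures drift times, not cross sections;
the standards of known CCS anchor the linear conversion.  The packaged
table holds the five doubly protonated polyalanine calibrants and the
drift times of ten doubly protonated PA-glycans.
"""

import pandas as pd

from glycoccs import apply_calibration, fit_calibration
from glycoccs.calibration import read_calibrant_table
from glycoccs.pipeline import _resolve

series = read_calibrant_table(_resolve("builtin:calibrants_polyalanine.csv"))
model = fit_calibration(series)
print(f"CCS = {model.slope:.1f} x t + {model.intercept:.0f}   "
      f"(R^2 = {model.r_squared:.3f}, n = {model.n_points})")

analytes = pd.read_csv(_resolve("builtin:glycan_drift_times.csv"))
ccs = apply_calibration(model, analytes["drift_ms"])
for species, t, c in zip(analytes["species"], analytes["drift_ms"], ccs):
    print(f"  {species:<10s} t = {t:.2f} ms -> CCS = {c:6.1f} A^2 ({round(c)})")

# The slope (~41 A^2/ms) converts each millisecond of drift into cross
# section; the rounded values are the glycans' experimental N2 CCSs.
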