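"""Trajectory-method CCS: classical scattering in the molecular potential.

Buffer-gas probes are shot through the Lennard-Jones + ion-induced-dipole
potential of the molecule; the momentum-transfer average of 1 - cos(chi)
over orientations, impact parameters and thermal speeds gives the
collision integral Omega(1,1).  Charges matter: the induced-dipole term
grows the cross section, most visibly in N2 (higher polarizability).
"""

import numpy as np

from glycoccs import TrajectoryParams, ccs_trajectory, load_gas

coords = np.column_stack([2.5 * np.arange(4), np.zeros(4), np.zeros(4)])
elements = ["C"] * 4
params = TrajectoryParams(seed=1, n_points=25, min_cycles=12, max_cycles=12)

for gas_name in ("He", "N2"):
    gas = load_gas(gas_name, temperature=300.0)
    neutral = ccs_trajectory(coords, elements, np.zeros(4), gas, params)
    charged = ccs_trajectory(coords, elements, np.full(4, 0.5), gas, params)
    print(f"{gas_name}: neutral {neutral.omega:6.1f} +- {neutral.standard_error:.1f} A^2   "
          f"charged(+2) {charged.omega:6.1f} +- {charged.standard_error:.1f} A^2   "
          f"(failed trajectories: {neutral.n_failed + charged.n_failed})")
# N2 cross sections exceed He ones (larger LJ wells, more polarizable gas),
# and the +2 charge enlarges both through the induced-dipole attraction.
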