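# Buffer-gas interaction parameters for the CCS engines.
#
# Each gas is a single structureless particle: exact for He; for N2 an
# effective isotropic pseudo-atom carrying the N2 mass and polarizability,
# with per-element 12-6 Lennard-Jones parameters chosen as effective
# single-site values in the spirit of the standard He and N2
# trajectory-method parameterizations.  collision_radius_A is the combined
# hard-sphere radius (atom + gas) used by the projection approximation.
# All values are defaults and may be overridden with a user file of the
# same layout (pass params_file= to glycoccs.gas.load_gas).
gases:
  He:
    mass_amu: 4.002602
    polarizability_A3: 0.205
    elements:
      H:  {epsilon_meV: 0.65, sigma_A: 2.38,  collision_radius_A: 2.20}
      C:  {epsilon_meV: 1.34, sigma_A: 3.043, collision_radius_A: 2.70}
      N:  {epsilon_meV: 1.34, sigma_A: 3.043, collision_radius_A: 2.70}
      O:  {epsilon_meV: 1.34, sigma_A: 3.043, collision_radius_A: 2.70}
      S:  {epsilon_meV: 1.35, sigma_A: 3.50,  collision_radius_A: 3.00}
      P:  {epsilon_meV: 1.35, sigma_A: 3.50,  collision_radius_A: 3.00}
  N2:
    mass_amu: 28.0134
    polarizability_A3: 1.710
    elements:
      H:  {epsilon_meV: 1.70, sigma_A: 2.80, collision_radius_A: 2.60}
      C:  {epsilon_meV: 4.20, sigma_A: 3.55, collision_radius_A: 3.10}
      N:  {epsilon_meV: 4.60, sigma_A: 3.40, collision_radius_A: 3.10}
      O:  {epsilon_meV: 5.20, sigma_A: 3.30, collision_radius_A: 3.10}
      S:  {epsilon_meV: 5.00, sigma_A: 3.70, collision_radius_A: 3.40}
      P:  {epsilon_meV: 5.00, sigma_A: 3.70, collision_radius_A: 3.40}
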