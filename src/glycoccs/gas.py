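"""Buffer-gas models and unit conventions for the CCS engines.

Internal unit system: length Å, time ps, mass unified atomic mass units
(u), energy kJ/mol.  With these choices

* kinetic energy  E = 0.005 · m[u] · v[Å/ps]²  (kJ/mol),
* acceleration    a[Å/ps²] = 100 · F[kJ/mol/Å] / m[u],
* Boltzmann constant k_B = 0.008314462618 kJ/mol/K,
* Coulomb energy of two unit charges at 1 Å: 1389.354576 kJ/mol.

The buffer gas is modeled as a single structureless particle — exact
for helium, an effective isotropic (pseudo-atom) approximation for N₂,
whose mass, polarizability and per-element Lennard-Jones parameters are
tabulated in ``data/gas_params.yaml`` and may be overridden by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ParameterError

KB_KJMOL = 0.008314462618          # kJ/mol/K
COULOMB_KJMOL_A = 1389.35457644    # kJ·Å/mol per e²
KJMOL_PER_MEV = 0.09648533212      # kJ/mol per meV (per particle)
KE_FACTOR = 0.005                  # E_kin = KE_FACTOR * m * v^2  (u, Å/ps -> kJ/mol)
ACC_FACTOR = 100.0                 # a = ACC_FACTOR * F / m      (kJ/mol/Å, u -> Å/ps²)


@dataclass(frozen=True)
class ElementParams:
    """Per-element gas interaction parameters.

    epsilon/sigma are the 12-6 Lennard-Jones pair parameters of the
    atom with the gas particle (epsilon in kJ/mol, sigma in Å);
    collision_radius is the combined hard-sphere radius (atom + gas)
    used by the projection approximation.
    """

    epsilon: float
    sigma: float
    collision_radius: float


@dataclass(frozen=True)
class GasModel:
    """A buffer gas at a temperature, with its per-element parameter table."""

    name: str
    mass: float            # u
    temperature: float     # K
    polarizability: float  # Å³
    element_params: dict[str, ElementParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("gas temperature must be positive")
        if self.mass <= 0:
            raise ParameterError("gas mass must be positive")

    def params_for(self, element: str) -> ElementParams:
        try:
            return self.element_params[element.upper()]
        except KeyError:
            raise ParameterError(
                f"gas {self.name!r} has no interaction parameters for element {element!r}"
            ) from None

    def collision_radius(self, element: str) -> float:
        return self.params_for(element).collision_radius

    def reduced_mass(self, molecular_mass: float) -> float:
        """Reduced mass of the gas-molecule pair in u."""
        return self.mass * molecular_mass / (self.mass + molecular_mass)


def _builtin_params_path() -> Path:
    return Path(str(resources.files("glycoccs").joinpath("data/gas_params.yaml")))


def load_gas(name: str, temperature: float = 300.0,
             params_file: str | Path | None = None) -> GasModel:
    """Load a gas model ('He' or 'N2') from the packaged or a user parameter file."""
    path = Path(params_file) if params_file is not None else _builtin_params_path()
    data = yaml.safe_load(path.read_text())
    gases = data.get("gases", {})
    if name not in gases:
        raise ParameterError(f"gas {name!r} not found in {path}; available: {sorted(gases)}")
    g = gases[name]
    elements = {}
    for elem, p in g.get("elements", {}).items():
        try:
            elements[str(elem).upper()] = ElementParams(
                epsilon=float(p["epsilon_meV"]) * KJMOL_PER_MEV,
                sigma=float(p["sigma_A"]),
                collision_radius=float(p["collision_radius_A"]),
            )
        except KeyError as exc:
            raise ParameterError(f"element {elem} in {path} missing field {exc}") from exc
    return GasModel(
        name=name,
        mass=float(g["mass_amu"]),
        temperature=float(temperature),
        polarizability=float(g["polarizability_A3"]),
        element_params=elements,
    )
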