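"""Collision-cross-section engines: projection approximation and trajectory method.

Two estimators of the orientation-averaged momentum-transfer collision
cross section Ω of a rigid ion in a buffer gas:

* **Projection approximation** — Ω is the rotationally averaged area of
  the projection of atom-centered hard disks of combined (atom + gas)
  radius.  Cheap, ignores long-range attraction and multiple scattering;
  historically used with He.

* **Trajectory method** — Ω is the first momentum-transfer collision
  integral Ω^(1,1): classical gas-particle trajectories are propagated
  through an atomistic potential (12-6 Lennard-Jones plus the
  ion-induced-dipole term from the per-atom partial charges and the gas
  polarizability), and 1 − cos χ of the scattering angle χ is averaged
  over Monte Carlo samples of molecular orientation, impact parameter
  (area-uniform on [0, b_max]) and relative speed (g⁵·exp(−μg²/2kT)
  weight, sampled exactly via a Gamma(3) draw).

Both are seeded and fully deterministic for a fixed seed.  Coordinates
are centered internally, making results exactly invariant to rigid
translation of the input at fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import ATOMIC_MASSES, ConformerEnsemble
from .errors import ConfigError, GeometryError, ParameterError
from .gas import ACC_FACTOR, COULOMB_KJMOL_A, KB_KJMOL, KE_FACTOR, GasModel

__all__ = [
    "TrajectoryParams", "CCSResult", "TrajectoryOutcome",
    "ccs_projection", "interaction_potential", "make_potential",
    "propagate_trajectory", "ccs_trajectory", "ccs_for_conformers",
]

#: Probe closer than this to any atom is treated as inside the hard core.
HARD_CORE = 0.1  # Å


@dataclass(frozen=True)
class TrajectoryParams:
    """Monte Carlo and integrator controls for the trajectory method.

    ``n_points`` is the number of (orientation, b, g) samples per Monte
    Carlo cycle; cycles are repeated until the standard error over cycle
    means drops below ``target_rel_se``·Ω or ``max_cycles`` is reached.
    ``b_pad`` and ``start_pad`` (Å) set b_max = extent + σ_max + b_pad
    and the trajectory start plane z₀ = −(b_max + start_pad).
    """

    n_points: int = 25
    min_cycles: int = 8
    max_cycles: int = 40
    target_rel_se: float = 0.01
    rtol: float = 1e-10
    atol: float = 1e-12
    energy_drift_tol: float = 1e-6
    b_pad: float = 10.0
    start_pad: float = 5.0
    time_factor: float = 40.0
    max_resample: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.max_cycles < 1:
            raise ConfigError("sample and cycle counts must be positive")


@dataclass(frozen=True)
class CCSResult:
    """An orientation-averaged CCS with its Monte Carlo standard error."""

    method: str            # 'projection' | 'trajectory'
    gas: str
    omega: float           # Å²
    standard_error: float  # Å²
    n_samples: int
    n_failed: int = 0      # non-escaping / non-conserving trajectories resampled
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.omega < 0 or self.standard_error < 0:
            raise GeometryError("CCS and its standard error must be non-negative")


@dataclass(frozen=True)
class TrajectoryOutcome:
    """One classical scattering trajectory: angle, escape flag, energy drift."""

    chi: float             # rad
    escaped: bool
    energy_drift: float    # |E_end - E_start| / |E_start|


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation matrix (normalized Gaussian quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# Projection approximation
# ---------------------------------------------------------------------------

def ccs_projection(coords: np.ndarray, elements: Sequence[str], gas: GasModel,
                   n_orientations: int = 300, n_darts: int = 4000, seed: int = 0,
                   radii: np.ndarray | None = None) -> CCSResult:
    """Projection-approximation CCS by Monte Carlo dart throwing.

    For each uniformly random orientation the molecule is projected onto
    a plane and the area of the union of disks of per-element combined
    collision radius is estimated by uniform darts in the bounding box;
    Ω is the orientation average, the standard error comes from the
    orientation-level variance (which dominates the dart-level one).

    ``radii`` overrides the per-element combined radii atom-by-atom.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if radii is None:
        radii = np.array([gas.collision_radius(e) for e in elements], dtype=float)
    else:
        radii = np.asarray(radii, dtype=float)
    if radii.shape[0] != coords.shape[0]:
        raise ParameterError("need one collision radius per atom")
    coords = coords - coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    r2 = radii ** 2
    rmax = radii.max()
    areas = np.empty(n_orientations)
    for k in range(n_orientations):
        rot = _random_rotation(rng)
        xy = coords @ rot.T[:, :2]
        lo = xy.min(axis=0) - rmax
        hi = xy.max(axis=0) + rmax
        box = float(np.prod(hi - lo))
        darts = rng.uniform(lo, hi, size=(n_darts, 2))
        d2 = ((darts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        hits = np.any(d2 <= r2[None, :], axis=1).mean()
        areas[k] = box * hits
    omega = float(areas.mean())
    se = float(areas.std(ddof=1) / math.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CCSResult("projection", gas.name, omega, se, n_orientations * n_darts)


# ---------------------------------------------------------------------------
# Interaction potential
# ---------------------------------------------------------------------------

def make_potential(coords: np.ndarray, epsilon: np.ndarray, sigma: np.ndarray,
                   charges: np.ndarray, polarizability: float,
                   ) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Build V(p), -∇V(p) for a gas probe at position p (all arrays per atom).

    V = Σᵢ 4εᵢ[(σᵢ/rᵢ)¹² − (σᵢ/rᵢ)⁶] − (α/2)·k_C·|Σᵢ qᵢ r̂ᵢ/rᵢ²|²

    with rᵢ the probe-atom distance, α the gas polarizability (Å³) and
    k_C the Coulomb factor converting e²/Å to kJ/mol.  The force is the
    exact analytic negative gradient.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    epsilon = np.asarray(epsilon, dtype=float)
    sigma2 = np.asarray(sigma, dtype=float) ** 2
    charges = np.asarray(charges, dtype=float)
    charged = bool(np.any(charges != 0.0)) and polarizability != 0.0
    eye3 = np.eye(3)

    def potential(p: np.ndarray) -> tuple[float, np.ndarray]:
        d = p - coords                                  # (N, 3)
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < HARD_CORE ** 2):
            raise GeometryError("gas probe inside an atomic hard core (r < 0.1 Å)")
        inv_r2 = 1.0 / r2
        sr6 = (sigma2 * inv_r2) ** 3
        sr12 = sr6 * sr6
        energy = float(np.sum(4.0 * epsilon * (sr12 - sr6)))
        force = ((4.0 * epsilon * (12.0 * sr12 - 6.0 * sr6)) * inv_r2) @ d
        if charged:
            inv_r3 = inv_r2 * np.sqrt(inv_r2)
            qir3 = charges * inv_r3
            efield = qir3 @ d                           # e/Å²
            energy += -0.5 * polarizability * COULOMB_KJMOL_A * float(efield @ efield)
            jac = np.sum(qir3) * eye3 - 3.0 * np.einsum("i,ij,ik->jk", qir3 * inv_r2, d, d)
            force += polarizability * COULOMB_KJMOL_A * (jac @ efield)
        return energy, force

    return potential


def interaction_potential(coords: np.ndarray, elements: Sequence[str],
                          probe_position: np.ndarray, gas: GasModel,
                          charges: np.ndarray | None = None,
                          ) -> tuple[float, np.ndarray]:
    """Energy (kJ/mol) and force (kJ/mol/Å) on a gas probe at one position."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    params = [gas.params_for(e) for e in elements]
    eps = np.array([p.epsilon for p in params])
    sig = np.array([p.sigma for p in params])
    if charges is None:
        charges = np.zeros(len(coords))
    pot = make_potential(coords, eps, sig, np.asarray(charges, float), gas.polarizability)
    return pot(np.asarray(probe_position, dtype=float))


# ---------------------------------------------------------------------------
# Trajectory propagation
# ---------------------------------------------------------------------------

def propagate_trajectory(potential: Callable[[np.ndarray], tuple[float, np.ndarray]],
                         mass: float, position: np.ndarray, velocity: np.ndarray,
                         params: TrajectoryParams = TrajectoryParams(),
                         ) -> TrajectoryOutcome:
    """Integrate one classical gas-probe trajectory and return its scattering angle.

    The probe (reduced mass ``mass`` in u) starts in the asymptotic
    region and is propagated with adaptive Runge-Kutta (RK45) until it
    re-crosses its starting radius moving outward.  χ is the angle
    between the asymptotic incoming and outgoing velocities.  A
    trajectory that fails to escape within the time budget (orbiting)
    is returned with ``escaped=False``; callers resample it.
    """
    p0 = np.asarray(position, dtype=float)
    v0 = np.asarray(velocity, dtype=float)
    speed0 = float(np.linalg.norm(v0))
    if speed0 <= 0:
        raise GeometryError("probe must have non-zero initial speed")
    r_escape = float(np.linalg.norm(p0))
    e_start = KE_FACTOR * mass * speed0 ** 2 + potential(p0)[0]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        _, force = potential(y[:3])
        out = np.empty(6)
        out[:3] = y[3:]
        out[3:] = ACC_FACTOR * force / mass
        return out

    def escape(t: float, y: np.ndarray) -> float:
        return float(np.linalg.norm(y[:3])) - r_escape * (1.0 + 1e-9)

    escape.terminal = True  # type: ignore[attr-defined]
    escape.direction = 1.0  # type: ignore[attr-defined]

    t_max = params.time_factor * (2.0 * r_escape / speed0)
    sol = solve_ivp(rhs, (0.0, t_max), np.concatenate([p0, v0]), method="RK45",
                    rtol=params.rtol, atol=params.atol, events=escape)
    escaped = bool(sol.t_events[0].size > 0)
    y_end = sol.y[:, -1]
    v_end = y_end[3:]
    speed_end = float(np.linalg.norm(v_end))
    e_end = KE_FACTOR * mass * speed_end ** 2 + potential(y_end[:3])[0]
    drift = abs(e_end - e_start) / abs(e_start)
    cos_chi = float(np.clip(v0 @ v_end / (speed0 * speed_end), -1.0, 1.0))
    return TrajectoryOutcome(chi=math.acos(cos_chi), escaped=escaped, energy_drift=drift)


# ---------------------------------------------------------------------------
# Trajectory-method CCS
# ---------------------------------------------------------------------------

def ccs_trajectory(coords: np.ndarray, elements: Sequence[str], charges: np.ndarray,
                   gas: GasModel, params: TrajectoryParams = TrajectoryParams(),
                   molecular_mass: float | None = None) -> CCSResult:
    """Trajectory-method Ω^(1,1) by Monte Carlo over orientation, b and g.

    Ω = π b_max² ⟨1 − cos χ⟩ with b area-uniform on [0, b_max], the
    molecular orientation uniform on rotations, and the relative speed g
    drawn from the flux/momentum-weighted Maxwell–Boltzmann distribution
    p(g) ∝ g⁵ exp(−μg²/2kT).  The standard error is computed over cycle
    means; trajectories that orbit or fail the energy-conservation check
    are resampled and counted in ``n_failed``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(elements) != coords.shape[0]:
        raise ParameterError("need one element per atom")
    charges = np.zeros(len(coords)) if charges is None else np.asarray(charges, dtype=float)
    p_el = [gas.params_for(e) for e in elements]
    eps = np.array([p.epsilon for p in p_el])
    sig = np.array([p.sigma for p in p_el])

    coords = coords - coords.mean(axis=0)  # translation invariance at fixed seed
    extent = float(np.linalg.norm(coords, axis=1).max())
    b_max = extent + float(sig.max(initial=0.0)) + params.b_pad
    z0 = -(b_max + params.start_pad)
    if abs(z0) <= extent:
        raise ConfigError("start distance does not clear the molecular extent")

    if molecular_mass is None:
        try:
            molecular_mass = float(sum(ATOMIC_MASSES[e.upper()] for e in elements))
        except KeyError as exc:
            raise ParameterError(f"no atomic mass for element {exc}") from exc
    mu = gas.reduced_mass(molecular_mass)
    kt = KB_KJMOL * gas.temperature

    rng = np.random.default_rng(params.seed)
    cycle_means: list[float] = []
    n_failed = 0

    def one_sample() -> float:
        nonlocal n_failed
        for _ in range(params.max_resample):
            rot = _random_rotation(rng)
            b = b_max * math.sqrt(rng.uniform())
            g = math.sqrt(2.0 * kt * ACC_FACTOR * rng.gamma(3.0) / mu)
            pot = make_potential(coords @ rot.T, eps, sig, charges, gas.polarizability)
            out = propagate_trajectory(pot, mu, np.array([b, 0.0, z0]),
                                       np.array([0.0, 0.0, g]), params)
            if out.escaped and out.energy_drift <= params.energy_drift_tol:
                return 1.0 - math.cos(out.chi)
            n_failed += 1
        raise GeometryError("trajectory resampling budget exhausted (persistent orbiting)")

    for cycle in range(params.max_cycles):
        vals = [one_sample() for _ in range(params.n_points)]
        cycle_means.append(float(np.mean(vals)))
        if cycle + 1 >= params.min_cycles:
            grand = float(np.mean(cycle_means))
            se = float(np.std(cycle_means, ddof=1) / math.sqrt(len(cycle_means)))
            if grand <= 0.0 or se <= params.target_rel_se * grand:
                break

    area = math.pi * b_max ** 2
    omega = area * float(np.mean(cycle_means))
    se = area * float(np.std(cycle_means, ddof=1) / math.sqrt(len(cycle_means)))
    n_samples = len(cycle_means) * params.n_points
    warning = None
    if n_failed > 0.01 * n_samples:
        warning = (f"{n_failed} non-escaping/non-conserving trajectories resampled "
                   f"({100.0 * n_failed / n_samples:.1f}% of {n_samples} samples)")
    return CCSResult("trajectory", gas.name, max(omega, 0.0), se, n_samples,
                     n_failed=n_failed, warning=warning)


# ---------------------------------------------------------------------------
# Per-conformer driver
# ---------------------------------------------------------------------------

def ccs_for_conformers(ensemble: ConformerEnsemble, indices: Sequence[int],
                       method: str, gas: GasModel,
                       params: TrajectoryParams = TrajectoryParams(),
                       n_orientations: int = 300, n_darts: int = 4000,
                       ) -> list[CCSResult]:
    """One CCSResult per requested conformer, deterministic given the base seed.

    Per-conformer seeds are derived from ``params.seed`` and the
    conformer index, so duplicate indices give bitwise-identical
    results and the list order does not matter.
    """
    if method not in ("projection", "trajectory"):
        raise ConfigError(f"unknown CCS method {method!r}")
    elements = ensemble.elements
    charges = ensemble.charges
    mol_mass = ensemble.molecular_mass()
    results: list[CCSResult] = []
    for idx in indices:
        if not (0 <= idx < ensemble.n_conformers):
            raise ConfigError(f"conformer index {idx} out of range")
        sub_seed = int(np.random.SeedSequence([params.seed, int(idx)]).generate_state(1)[0]
                       % (2 ** 31))
        coords = ensemble.conformer(int(idx))
        if method == "projection":
            overrides = [a.radius_override for a in ensemble.atoms]
            radii = None
            if any(r is not None for r in overrides):
                radii = np.array([r if r is not None else gas.collision_radius(e)
                                  for r, e in zip(overrides, elements)])
            results.append(ccs_projection(coords, elements, gas, n_orientations,
                                          n_darts, seed=sub_seed, radii=radii))
        else:
            results.append(ccs_trajectory(coords, elements, charges, gas,
                                          replace(params, seed=sub_seed),
                                          molecular_mass=mol_mass))
    return results
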