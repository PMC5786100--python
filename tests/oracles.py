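"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (dense grids, exhaustive loops,
textbook quadrature) and shares no code with the implementation paths
it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import roots_genlaguerre


# ---------------------------------------------------------------------------
# Ordinary least squares, closed form with confidence interval
# ---------------------------------------------------------------------------

def ols_line(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS slope, intercept, and slope standard error."""
    t = np.asarray(t, float); c = np.asarray(c, float)
    n = t.size
    tbar, cbar = t.mean(), c.mean()
    sxx = ((t - tbar) ** 2).sum()
    slope = ((t - tbar) * (c - cbar)).sum() / sxx
    intercept = cbar - slope * tbar
    resid = c - slope * t - intercept
    s2 = (resid ** 2).sum() / (n - 2)
    return float(slope), float(intercept), float(math.sqrt(s2 / sxx))


# ---------------------------------------------------------------------------
# Dense-grid rasterized projection area
# ---------------------------------------------------------------------------

def raster_projection_area(xy: np.ndarray, radii: np.ndarray, pitch: float = 0.01) -> float:
    """Area of the union of disks by counting grid cells (cell centers)."""
    rmax = radii.max()
    lo = xy.min(axis=0) - rmax - pitch
    hi = xy.max(axis=0) + rmax + pitch
    xs = np.arange(lo[0], hi[0], pitch) + 0.5 * pitch
    ys = np.arange(lo[1], hi[1], pitch) + 0.5 * pitch
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = np.zeros(gx.shape, dtype=bool)
    for (cx, cy), r in zip(xy, radii):
        inside |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    return float(inside.sum()) * pitch * pitch


# ---------------------------------------------------------------------------
# Classical deflection angle and collision integral for one LJ center
# ---------------------------------------------------------------------------

def lj_deflection_angle(epsilon: float, sigma: float, energy: float, b: float,
                        n_nodes: int = 300) -> float:
    """χ(E, b) from the radial deflection integral (u = 1/r substitution).

    χ = π − 2b ∫₀^{u0} du / sqrt(1 − b²u² − V(1/u)/E) with u0 the
    outermost turning point; the endpoint singularity is removed with
    u = u0(1 − s²).
    """

    def v_of_u(u):
        sr6 = (sigma * np.asarray(u)) ** 6
        return 4.0 * epsilon * (sr6 ** 2 - sr6)

    def f(u):
        return 1.0 - (b * np.asarray(u)) ** 2 - v_of_u(u) / energy

    us = np.linspace(1e-9, 1.0 / (0.3 * sigma), 6000)
    fs = f(us)
    neg = np.where(fs <= 0)[0]
    if neg.size == 0:
        return 0.0
    i = neg[0]
    u0 = brentq(f, us[i - 1], us[i], xtol=1e-14)
    s, w = np.polynomial.legendre.leggauss(n_nodes)
    s = 0.5 * (s + 1.0)
    w = 0.5 * w
    u = np.clip(u0 * (1.0 - s ** 2), 1e-14, None)
    fu = np.clip(f(u), 1e-16, None)
    return math.pi - 2.0 * b * float(np.sum(w * 2.0 * u0 * s / np.sqrt(fu)))


def lj_collision_integral(epsilon: float, sigma: float, mu: float, temperature: float,
                          b_max: float, kb: float = 0.008314462618,
                          n_g: int = 12, n_b: int = 120) -> float:
    """Ω^(1,1) for a single LJ center by direct 2-D (g, b) quadrature.

    The relative-speed average uses the g⁵ exp(−μg²/2kT) weight,
    evaluated exactly with generalized Gauss–Laguerre nodes (α = 2) in
    x = μg²/2kT; the b integral is Gauss–Legendre on [0, b_max].
    Energies in kJ/mol with E = 0.005 μ g² (g in Å/ps, μ in u).
    """
    kt = kb * temperature
    xb, wb = np.polynomial.legendre.leggauss(n_b)
    b_nodes = 0.5 * (xb + 1.0) * b_max
    wb = 0.5 * wb * b_max

    def q_of_g(g: float) -> float:
        energy = 0.005 * mu * g * g
        total = 0.0
        for b, w in zip(b_nodes, wb):
            chi = lj_deflection_angle(epsilon, sigma, energy, b)
            total += w * (1.0 - math.cos(chi)) * 2.0 * math.pi * b
        return total

    x, w = roots_genlaguerre(n_g, 2.0)
    omega = sum(wi * q_of_g(math.sqrt(2.0 * kt * 100.0 * xi / mu)) for xi, wi in zip(x, w))
    return float(omega / 2.0)  # Γ(3) = 2 normalizes the weight


# ---------------------------------------------------------------------------
# Exhaustive hydrogen-bond triple scan
# ---------------------------------------------------------------------------

def brute_force_hbonds(coords: np.ndarray, elements: list[str], residues: np.ndarray,
                       r_max: float = 3.5, theta_max: float = 30.0,
                       donor_elements: set[str] = frozenset({"N", "O"}),
                       exclude_intra_residue: bool = True) -> set[tuple[int, int, int]]:
    """All (donor, H, acceptor) triples satisfying the geometric criterion.

    Plain O(N³) loops: every hydrogen is matched to its nearest heavy
    atom (within 1.2 Å), kept if that parent is a donor element, and
    tested against every candidate acceptor.
    """
    n = len(elements)
    found = set()
    for h in range(n):
        if elements[h] != "H":
            continue
        best, best_d = None, 1.2
        for x in range(n):
            if elements[x] == "H":
                continue
            d = float(np.linalg.norm(coords[h] - coords[x]))
            if d <= best_d:
                best, best_d = x, d
        if best is None or elements[best] not in donor_elements:
            continue
        donor = best
        for y in range(n):
            if y == donor or elements[y] not in donor_elements:
                continue
            if exclude_intra_residue and residues[y] == residues[donor]:
                continue
            r = float(np.linalg.norm(coords[y] - coords[donor]))
            if r >= r_max:
                continue
            xh = coords[h] - coords[donor]
            xy = coords[y] - coords[donor]
            cos_t = float(xh @ xy / (np.linalg.norm(xh) * np.linalg.norm(xy)))
            theta = math.degrees(math.acos(max(min(cos_t, 1.0), -1.0)))
            if theta < theta_max:
                found.add((donor, h, y))
    return found


# ---------------------------------------------------------------------------
# Rotation-space grid search for the optimal-superposition RMSD
# ---------------------------------------------------------------------------

def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def grid_search_min_rmsd(ref: np.ndarray, mob: np.ndarray, n_grid: int = 3000,
                         seed: int = 0) -> float:
    """Minimal RMSD over rotations: random quaternion grid + simplex refinement."""
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    n = a.shape[0]

    def cost(q: np.ndarray) -> float:
        rot = _quat_to_matrix(q)
        return float(np.sqrt(((a - b @ rot.T) ** 2).sum() / n))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    vals = np.array([cost(q) for q in quats])
    best = quats[int(vals.argmin())]
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def brute_force_medoid(aligned: np.ndarray, members: np.ndarray,
                       rmsd_fn) -> int:
    """Exhaustive medoid: member minimizing mean pairwise RMSD to co-members."""
    best, best_val = int(members[0]), math.inf
    for i in members:
        val = np.mean([rmsd_fn(aligned[i], aligned[j]) for j in members if j != i]) \
            if members.size > 1 else 0.0
        if val < best_val:
            best, best_val = int(i), float(val)
    return best
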