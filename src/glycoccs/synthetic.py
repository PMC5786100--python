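"""Synthetic fixtures with full ground truth.

The pipeline's real inputs (replica-exchange trajectory snapshots of
PA-glycans) are not deposited anywhere, so every test fixture is
generated: linear calibrant series with optional Gaussian noise,
multi-conformer ensembles that are mixtures of a small number of rigid
reference structures plus coordinate noise with known mixture weights,
branched bead-chain glycan mimics with annotated arms, and planted
donor-H-acceptor geometries at exactly controlled distance and angle.

Bead "residues" are small rigid C/O/H groups, not real sugars: the
downstream operators only ever inspect elements, charges, coordinates
and unit labels.  All generators are deterministic for a fixed seed and
consume one shared random stream in a documented order (state labels
first, then noise), so the recorded ground truth is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrantSeries
from .ensemble import AtomRecord, ConformerEnsemble, ResidueAnnotation
from .errors import DomainError, GeometryError
from .analysis import rmsd

__all__ = [
    "GroundTruth", "PlantedHBond", "make_calibrants", "make_two_state_ensemble",
    "make_glycan_mimic", "plant_hbond",
]


@dataclass(frozen=True)
class PlantedHBond:
    """Record of one planted donor-H-acceptor group."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float          # requested R_XY, Å
    angle: float             # requested θ_HXY, degrees
    frames: tuple[int, ...]  # conformers in which the geometry is realized


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle comparisons."""

    state_labels: list[int] | None = None
    state_counts: dict[int, int] | None = None
    planted_hbonds: list[PlantedHBond] = field(default_factory=list)
    true_slope: float | None = None
    true_intercept: float | None = None
    state_ccs: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# Calibrants
# ---------------------------------------------------------------------------

def make_calibrants(slope: float = 41.3, intercept: float = 152.0, n: int = 5,
                    drift_range: tuple[float, float] = (3.5, 4.7),
                    noise_sigma: float = 0.0, seed: int = 0,
                    ) -> tuple[CalibrantSeries, GroundTruth]:
    """Calibrant series on a known line: CCS = slope·t + intercept + N(0, σ).

    Drift times are evenly spaced across ``drift_range`` (ms); noise is
    in Å² on the CCS axis, matching the OLS error model of the fit.
    """
    if n < 2:
        raise DomainError(f"need at least 2 calibrants, got {n}")
    lo, hi = drift_range
    if not (0 < lo < hi):
        raise DomainError(f"invalid drift range {drift_range}")
    if noise_sigma < 0:
        raise DomainError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.linspace(lo, hi, n)
    ccs = slope * t + intercept + rng.normal(0.0, noise_sigma, size=n)
    series = CalibrantSeries(
        species=tuple(f"cal{i}" for i in range(n)),
        mz=tuple(300.0 + 35.0 * i for i in range(n)),
        drift_ms=tuple(float(x) for x in t),
        ccs_A2=tuple(float(c) for c in ccs),
    )
    return series, GroundTruth(true_slope=slope, true_intercept=intercept)


# ---------------------------------------------------------------------------
# Two-state mixture ensembles
# ---------------------------------------------------------------------------

def _bead_helix(n_atoms: int, spacing: float = 3.0) -> np.ndarray:
    """A gently helical carbon bead chain (non-collinear, self-avoiding)."""
    radius = 4.0
    dtheta = 2.0 * math.asin(min(spacing * 0.4 / radius, 0.95))
    dz = math.sqrt(max(spacing ** 2 - (2 * radius * math.sin(dtheta / 2)) ** 2, 0.25))
    theta = dtheta * np.arange(n_atoms)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), dz * np.arange(n_atoms)])


def make_two_state_ensemble(n_frames: int, weight_a: float = 0.6,
                            rmsd_separation: float = 10.0, noise_sigma: float = 0.1,
                            seed: int = 0, n_atoms: int = 20,
                            state_ccs: tuple[float, float] | None = None,
                            ) -> tuple[ConformerEnsemble, GroundTruth]:
    """Mixture of two rigid bead-chain conformations with known weights.

    State B is state A plus a scaled smooth deformation, with the scale
    solved (bisection) so the pairwise *fitted* RMSD equals
    ``rmsd_separation`` essentially exactly.  Frames draw their state
    label first (shared stream), then per-atom Gaussian noise of width
    ``noise_sigma``; labels and counts are recorded in the ground truth.
    """
    if not (0.0 <= weight_a <= 1.0):
        raise DomainError("weight_a must lie in [0, 1]")
    if rmsd_separation <= 0:
        raise DomainError("separation must be positive")
    if n_frames < 1:
        raise DomainError("need at least one frame")
    ref_a = _bead_helix(n_atoms)
    extent = float(np.linalg.norm(ref_a - ref_a.mean(0), axis=1).max())
    if rmsd_separation > 5.0 * extent:
        raise GeometryError(
            f"separation {rmsd_separation} Å unattainable for a chain of extent {extent:.1f} Å"
        )
    # smooth low-frequency deformation; deterministic, independent of `seed`
    phase = np.arange(n_atoms) / max(n_atoms - 1, 1)
    delta = np.column_stack([
        np.sin(2.0 * math.pi * phase),
        np.cos(3.0 * math.pi * phase) - 1.0,
        phase ** 2,
    ])
    delta -= delta.mean(axis=0)

    def fitted(scale: float) -> float:
        return rmsd(ref_a, ref_a + scale * delta, fit=True)

    lo_s, hi_s = 0.0, 1.0
    while fitted(hi_s) < rmsd_separation:
        hi_s *= 2.0
        if hi_s > 1e6:  # pragma: no cover - guarded by the extent check above
            raise GeometryError("cannot reach requested separation")
    for _ in range(200):
        mid = 0.5 * (lo_s + hi_s)
        if fitted(mid) < rmsd_separation:
            lo_s = mid
        else:
            hi_s = mid
    ref_b = ref_a + 0.5 * (lo_s + hi_s) * delta

    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) >= weight_a).astype(int)  # 0 = A, 1 = B
    refs = (ref_a, ref_b)
    coords = np.stack([refs[lab] + rng.normal(0.0, noise_sigma, size=(n_atoms, 3))
                       for lab in labels])
    atoms = [AtomRecord(atom_index=i, element="C", atom_name="C",
                        residue_index=i + 1, residue_name="BEA")
             for i in range(n_atoms)]
    ensemble = ConformerEnsemble(atoms, coords,
                                 labels=[("A", "B")[lab] for lab in labels])
    truth = GroundTruth(
        state_labels=[int(lab) for lab in labels],
        state_counts={0: int((labels == 0).sum()), 1: int((labels == 1).sum())},
        state_ccs=state_ccs,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Branched glycan mimics
# ---------------------------------------------------------------------------

#: local geometry of one rigid bead residue: C center, hydroxyl O, its H.
_RESIDUE_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],        # C
    [1.4, 0.0, 0.0],        # O
    [1.4 + 0.32, 0.905, 0.0],  # H (0.96 Å from O)
])
_RESIDUE_ELEMENTS = ("C", "O", "H")


def make_glycan_mimic(core_length: int = 2, arm13_length: int = 3,
                      arm16_length: int = 2, fucose: bool = False,
                      seed: int = 0, max_retries: int = 50,
                      ) -> tuple[ConformerEnsemble, ResidueAnnotation]:
    """Branched bead-residue chain mimicking an N-glycan's unit topology.

    Residue 1 is the reducing-end PA tag, followed by a linear core of
    ``core_length`` residues; the two arms branch from the core
    terminus, and an optional fucose bead hangs off the first core
    residue.  Each residue is a rigid C/O/H group (a hydroxyl donor and
    acceptor), randomly oriented; geometry is jittered and retried until
    no two atoms of different residues come within 1.5 Å.
    """
    if min(core_length, arm13_length, arm16_length) < 1:
        raise DomainError("all unit lengths must be >= 1")
    step = 3.8
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        centers: list[np.ndarray] = []
        labels: list[str] = []

        centers.append(np.zeros(3)); labels.append("PA-tag")
        for i in range(core_length):
            centers.append(np.array([step * (i + 1), 0.0, 0.0]))
            labels.append("core-chitobiose")
        branch = centers[-1]
        d13 = np.array([0.55, 0.78, 0.30]); d13 /= np.linalg.norm(d13)
        d16 = np.array([0.55, -0.78, -0.30]); d16 /= np.linalg.norm(d16)
        for i in range(arm13_length):
            centers.append(branch + step * (i + 1) * d13); labels.append("alpha1-3-arm")
        for i in range(arm16_length):
            centers.append(branch + step * (i + 1) * d16); labels.append("alpha1-6-arm")
        if fucose:
            centers.append(centers[1] + np.array([0.0, 0.0, step])); labels.append("fucose")

        atoms: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        owner: list[int] = []
        for res_idx, (center, label) in enumerate(zip(centers, labels), start=1):
            jitter = rng.normal(0.0, 0.25, size=3)
            q = rng.normal(size=4); q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            local = _RESIDUE_TEMPLATE @ rot.T + center + jitter
            for elem, pos in zip(_RESIDUE_ELEMENTS, local):
                atoms.append(AtomRecord(atom_index=len(atoms), element=elem,
                                        atom_name=elem, residue_index=res_idx,
                                        residue_name=label[:3].upper()))
                coords.append(pos)
                owner.append(res_idx)
        pts = np.asarray(coords)
        own = np.asarray(owner)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        inter = own[:, None] != own[None, :]
        if np.all(d[inter] >= 1.5):
            annotation = ResidueAnnotation({r: lab for r, lab in
                                            enumerate(labels, start=1)})
            return ConformerEnsemble(atoms, pts[None, :, :]), annotation
    raise GeometryError(f"could not build a self-avoiding mimic in {max_retries} attempts")


# ---------------------------------------------------------------------------
# Planted hydrogen bonds
# ---------------------------------------------------------------------------

def plant_hbond(ensemble: ConformerEnsemble, donor_residue: int, acceptor_residue: int,
                r_xy: float, theta: float, frames: list[int] | None = None,
                ) -> tuple[ConformerEnsemble, PlantedHBond]:
    """Append an O-H donor group and an O acceptor with exact (R_XY, θ_HXY).

    The three atoms are placed on an outward axis well clear of the
    existing structure (collision-checked at 1.5 Å), with the realized
    distance and donor-centered angle equal to the request to machine
    precision.  In frames not listed in ``frames`` (default: all) the
    acceptor is displaced far along the axis so no bond is present
    there — which is what makes fractional-occupancy fixtures possible.
    """
    if not (0.5 < r_xy < 20.0) or not (0.0 <= theta < 90.0):
        raise DomainError(f"unphysical planted geometry R={r_xy}, theta={theta}")
    residues = set(int(x) for x in ensemble.residue_indices)
    for res in (donor_residue, acceptor_residue):
        if res not in residues:
            raise DomainError(f"residue {res} not present in ensemble")
    m = ensemble.n_conformers
    frames_t = tuple(range(m)) if frames is None else tuple(sorted(set(frames)))
    if any(f < 0 or f >= m for f in frames_t):
        raise DomainError("frame index out of range")

    coords0 = ensemble.conformer(0)
    center = coords0.mean(axis=0)
    extent = float(np.linalg.norm(coords0 - center, axis=1).max())
    # deterministic outward direction, distinct per planted group
    k = sum(1 for a in ensemble.atoms if a.atom_name == "OPL")
    golden = math.pi * (3.0 - math.sqrt(5.0))
    zc = 1.0 - 2.0 * ((k % 16) + 0.5) / 16.0
    rc = math.sqrt(1.0 - zc * zc)
    u = np.array([rc * math.cos(golden * k), rc * math.sin(golden * k), zc])
    w = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(u, [0.0, 1.0, 0.0])
    w /= np.linalg.norm(w)

    donor_pos = center + (extent + 6.0) * u
    acceptor_pos = donor_pos + r_xy * u
    th = math.radians(theta)
    h_pos = donor_pos + 0.96 * (math.cos(th) * u + math.sin(th) * w)
    far_pos = donor_pos + (r_xy + 10.0) * u

    for frame in range(m):
        old = ensemble.conformer(frame)
        for p in (donor_pos, h_pos):
            if np.linalg.norm(old - p, axis=1).min() < 1.5:
                raise GeometryError("planted group collides with existing atoms")

    n0 = ensemble.n_atoms
    atoms = list(ensemble.atoms) + [
        AtomRecord(n0, "O", "OPL", donor_residue, "PLT"),
        AtomRecord(n0 + 1, "H", "HPL", donor_residue, "PLT"),
        AtomRecord(n0 + 2, "O", "OPA", acceptor_residue, "PLT"),
    ]
    new_coords = np.empty((m, n0 + 3, 3))
    new_coords[:, :n0, :] = ensemble.coords
    new_coords[:, n0, :] = donor_pos
    new_coords[:, n0 + 1, :] = h_pos
    for frame in range(m):
        new_coords[frame, n0 + 2, :] = acceptor_pos if frame in frames_t else far_pos
    labels = list(ensemble.labels) if ensemble.labels else None
    planted = PlantedHBond(donor=n0, hydrogen=n0 + 1, acceptor=n0 + 2,
                           distance=r_xy, angle=theta, frames=frames_t)
    return ConformerEnsemble(atoms, new_coords, labels=labels), planted
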