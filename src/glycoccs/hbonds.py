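"""Geometric hydrogen-bond detection, occupancy maps and category summaries.

A hydrogen bond X–H···Y is recorded when the heavy-atom distance
R_XY < R_max (default 3.5 Å) and the angle θ_HXY between the X–H bond
vector and the X–Y vector is below θ_max (default 30°).  The angle is
donor-centered — measured at X between X→H and X→Y — not the common
alternative measured at the hydrogen.  Donor and acceptor elements
default to {N, O}; intra-residue bonds are excluded by default.

Residue-pair occupancy is the fraction of conformers with at least one
bond between the pair (bond multiplicity is reported separately as a
per-pair mean count).  Category percentages pool bonds across all
conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ensemble import ConformerEnsemble, ResidueAnnotation
from .errors import CoverageError, GeometryError

__all__ = [
    "HBondCriteria", "HBond", "HBondMap", "CategorySummary",
    "assign_donors_hydrogens", "detect_hbonds", "hbond_occupancy_map",
    "categorize_hbonds", "compare_shape_hbonds",
]

#: Category keys of the inter-unit summary, in report order.
CATEGORIES = ("core-alpha1-6", "core-alpha1-3", "alpha1-3-alpha1-6", "intra-arm")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: R_XY < r_max and θ_HXY < theta_max (degrees)."""

    r_max: float = 3.5
    theta_max: float = 30.0
    donor_acceptor_elements: frozenset[str] = frozenset({"N", "O"})
    covalent_xh_max: float = 1.2       # Å, H-to-parent assignment radius
    exclude_intra_residue: bool = True

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise GeometryError("r_max must be positive")
        if not (0.0 < self.theta_max < 90.0):
            raise GeometryError("theta_max must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HBond:
    donor: int       # heavy atom X index
    hydrogen: int
    acceptor: int    # heavy atom Y index
    distance: float  # R_XY, Å
    angle: float     # θ_HXY, degrees
    conformer: int


@dataclass(frozen=True)
class HBondMap:
    """Symmetric residue-pair occupancy probabilities over an ensemble."""

    occupancy: dict[tuple[int, int], float]
    mean_count: dict[tuple[int, int], float]
    n_conformers: int
    residues: tuple[int, ...]

    def get(self, i: int, j: int) -> float:
        return self.occupancy.get((min(i, j), max(i, j)), 0.0)

    def matrix(self) -> np.ndarray:
        idx = {r: k for k, r in enumerate(self.residues)}
        out = np.zeros((len(self.residues), len(self.residues)))
        for (i, j), occ in self.occupancy.items():
            out[idx[i], idx[j]] = out[idx[j], idx[i]] = occ
        return out


@dataclass(frozen=True)
class CategorySummary:
    """Pooled inter-unit H-bond statistics for one ensemble.

    ``percentages`` covers the four inter-unit categories; bonds that
    involve a fucose residue fall outside them and are tallied in
    ``n_other`` (excluded from the percentages).  The PA tag counts with
    the core chitobiose.
    """

    avg_count: float                       # bonds per conformer, all bonds
    percentages: dict[str, float]          # over categorized bonds, sums to 100
    n_categorized: int
    n_other: int
    n_conformers: int

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.n_categorized > 0 and abs(total - 100.0) > 1e-9:
            raise GeometryError("category percentages must sum to 100")


def assign_donors_hydrogens(ensemble: ConformerEnsemble, conformer: int = 0,
                            criteria: HBondCriteria = HBondCriteria(),
                            ) -> list[tuple[int, int]]:
    """Assign each hydrogen to its covalent parent; keep donor-element parents.

    The parent is the nearest heavy atom within ``covalent_xh_max``
    (1.2 Å); a hydrogen with no heavy atom that close raises an
    orphan-hydrogen error, and a structure without hydrogens raises a
    missing-hydrogens error.  Pairs whose parent element is outside the
    donor/acceptor set (e.g. C–H) are dropped.
    """
    elements = ensemble.elements
    h_idx = np.where(elements == "H")[0]
    if h_idx.size == 0:
        raise CoverageError("structure contains no hydrogens; cannot assign donors")
    heavy_idx = np.where(elements != "H")[0]
    if heavy_idx.size == 0:
        raise GeometryError("structure contains no heavy atoms")
    coords = ensemble.conformer(conformer)
    d = np.linalg.norm(coords[h_idx][:, None, :] - coords[heavy_idx][None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    pairs: list[tuple[int, int]] = []
    for k, h in enumerate(h_idx):
        if d[k, nearest[k]] > criteria.covalent_xh_max:
            raise GeometryError(
                f"orphan hydrogen {int(h)}: no heavy atom within "
                f"{criteria.covalent_xh_max} Å (nearest at {d[k, nearest[k]]:.2f} Å)"
            )
        parent = int(heavy_idx[nearest[k]])
        if elements[parent] in criteria.donor_acceptor_elements:
            pairs.append((parent, int(h)))
    return pairs


def detect_hbonds(ensemble: ConformerEnsemble, conformer: int = 0,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All X–H···Y triples of one conformer satisfying the geometric criterion."""
    pairs = assign_donors_hydrogens(ensemble, conformer, criteria)
    elements = ensemble.elements
    residues = ensemble.residue_indices
    coords = ensemble.conformer(conformer)
    acceptors = np.where(np.isin(elements, sorted(criteria.donor_acceptor_elements)))[0]
    cos_max = math.cos(math.radians(criteria.theta_max))
    bonds: list[HBond] = []
    for donor, hydrogen in pairs:
        xy = coords[acceptors] - coords[donor]
        r = np.linalg.norm(xy, axis=1)
        xh = coords[hydrogen] - coords[donor]
        xh_norm = np.linalg.norm(xh)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_theta = xy @ xh / (r * xh_norm)
        ok = (r < criteria.r_max) & (cos_theta > cos_max) & (acceptors != donor)
        if criteria.exclude_intra_residue:
            ok &= residues[acceptors] != residues[donor]
        for a_pos in np.where(ok)[0]:
            acceptor = int(acceptors[a_pos])
            bonds.append(HBond(
                donor=donor, hydrogen=hydrogen, acceptor=acceptor,
                distance=float(r[a_pos]),
                angle=float(math.degrees(math.acos(np.clip(cos_theta[a_pos], -1.0, 1.0)))),
                conformer=conformer,
            ))
    return bonds


def hbond_occupancy_map(ensemble: ConformerEnsemble,
                        criteria: HBondCriteria = HBondCriteria(),
                        annotation: ResidueAnnotation | None = None) -> HBondMap:
    """Residue-pair H-bond occupancy over all conformers of an ensemble.

    occupancy(i, j) = fraction of conformers with at least one bond
    between residues i and j in either direction.
    """
    if annotation is not None:
        annotation.validate_against(ensemble)
    residues = ensemble.residue_indices
    m = ensemble.n_conformers
    frame_hits: dict[tuple[int, int], int] = {}
    bond_counts: dict[tuple[int, int], int] = {}
    for f in range(m):
        seen: set[tuple[int, int]] = set()
        for bond in detect_hbonds(ensemble, f, criteria):
            i, j = int(residues[bond.donor]), int(residues[bond.acceptor])
            key = (min(i, j), max(i, j))
            bond_counts[key] = bond_counts.get(key, 0) + 1
            seen.add(key)
        for key in seen:
            frame_hits[key] = frame_hits.get(key, 0) + 1
    occupancy = {k: v / m for k, v in frame_hits.items()}
    mean_count = {k: v / m for k, v in bond_counts.items()}
    return HBondMap(occupancy=occupancy, mean_count=mean_count, n_conformers=m,
                    residues=tuple(sorted(set(int(r) for r in residues))))


def _category(unit_i: str, unit_j: str) -> str:
    """Map a pair of unit labels to a Table-style category key."""
    # PA tag is part of the reducing-end core for category purposes.
    u1 = "core-chitobiose" if unit_i == "PA-tag" else unit_i
    u2 = "core-chitobiose" if unit_j == "PA-tag" else unit_j
    if "fucose" in (u1, u2):
        return "other"
    if u1 == u2:
        return "intra-arm"
    pair = frozenset((u1, u2))
    if pair == frozenset({"core-chitobiose", "alpha1-6-arm"}):
        return "core-alpha1-6"
    if pair == frozenset({"core-chitobiose", "alpha1-3-arm"}):
        return "core-alpha1-3"
    if pair == frozenset({"alpha1-3-arm", "alpha1-6-arm"}):
        return "alpha1-3-alpha1-6"
    return "other"  # pragma: no cover - exhaustive over the five labels


def categorize_hbonds(bonds_per_conformer: Sequence[Iterable[HBond]],
                      annotation: ResidueAnnotation,
                      residue_indices: np.ndarray) -> CategorySummary:
    """Pool bonds across conformers into inter-unit category percentages.

    ``bonds_per_conformer`` is one bond list per conformer (e.g. from
    :func:`detect_hbonds` frame by frame); ``residue_indices`` maps atom
    index -> residue index for the shared topology.
    """
    counts = {c: 0 for c in CATEGORIES}
    n_other = 0
    n_total = 0
    for bonds in bonds_per_conformer:
        for bond in bonds:
            n_total += 1
            ri = int(residue_indices[bond.donor])
            rj = int(residue_indices[bond.acceptor])
            cat = _category(annotation.label(ri), annotation.label(rj))
            if cat == "other":
                n_other += 1
            else:
                counts[cat] += 1
    n_cat = sum(counts.values())
    percentages = {c: (100.0 * counts[c] / n_cat if n_cat else 0.0) for c in CATEGORIES}
    n_conf = max(len(bonds_per_conformer), 1)
    return CategorySummary(avg_count=n_total / n_conf, percentages=percentages,
                           n_categorized=n_cat, n_other=n_other,
                           n_conformers=len(bonds_per_conformer))


def compare_shape_hbonds(summary_globular: CategorySummary,
                         summary_rod: CategorySummary) -> dict[str, float]:
    """Globular-minus-rod differences in average bond count and category percentages."""
    out = {"avg_count": summary_globular.avg_count - summary_rod.avg_count}
    for cat in CATEGORIES:
        out[cat] = summary_globular.percentages[cat] - summary_rod.percentages[cat]
    return out
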