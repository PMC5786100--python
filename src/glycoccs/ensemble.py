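"""Core containers: atoms, conformer ensembles, and residue annotations.

A :class:`ConformerEnsemble` holds one shared atom table (elements,
names, residues, partial charges) and ``M`` coordinate sets of shape
``(N, 3)`` in Ångström.  Gas-phase conventions throughout: no periodic
boundaries, coordinates always in Å, charges in elementary-charge
units.  Atom indices are 0-based internally; file formats that count
from 1 (PDB serials) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AnnotationError, CoverageError, StructuralInconsistencyError

#: Recognized element symbols (ions/metals excluded on purpose: gas-phase
#: glycan ions contain only these plus the odd halogen).
KNOWN_ELEMENTS = {
    "H", "D", "B", "C", "N", "O", "F", "NA", "MG", "P", "S", "CL", "K", "CA",
    "BR", "I", "FE", "ZN", "SE",
}

#: Atomic masses in unified atomic mass units for the elements the CCS
#: engines accept.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974,
    "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078, "BR": 79.904,
    "I": 126.90, "FE": 55.845, "ZN": 65.38, "SE": 78.971,
}

#: The five structural-unit labels used to annotate glycan residues.
UNIT_LABELS = ("core-chitobiose", "alpha1-3-arm", "alpha1-6-arm", "fucose", "PA-tag")


def normalize_element(symbol: str) -> str:
    """Canonicalize an element symbol ('h', 'CL', 'Cl' -> 'H', 'CL', 'CL')."""
    return symbol.strip().upper()


@dataclass
class AtomRecord:
    """One atom of the shared topology.

    ``partial_charge`` is in elementary-charge units; ``radius_override``
    (Å), when set, replaces the per-gas collision radius in the
    projection engine.
    """

    atom_index: int
    element: str
    atom_name: str = ""
    residue_index: int = 1
    residue_name: str = "UNK"
    partial_charge: float = 0.0
    radius_override: float | None = None

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        if self.element not in KNOWN_ELEMENTS:
            raise StructuralInconsistencyError(
                f"atom {self.atom_index}: unrecognized element symbol {self.element!r}"
            )
        if not np.isfinite(self.partial_charge):
            raise StructuralInconsistencyError(
                f"atom {self.atom_index}: non-finite partial charge"
            )


@dataclass
class ConformerEnsemble:
    """Shared atom table plus ``M`` coordinate sets (Å)."""

    atoms: list[AtomRecord]
    coords: np.ndarray  # (M, N, 3)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralInconsistencyError(
                f"coordinates must have shape (M, N, 3); got {self.coords.shape}"
            )
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        m, n, _ = self.coords.shape
        if m < 1:
            raise StructuralInconsistencyError("ensemble must contain at least one conformer")
        if n != len(self.atoms):
            raise StructuralInconsistencyError(
                f"atom table has {len(self.atoms)} atoms but conformers have {n} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = int(np.argwhere(~np.isfinite(self.coords))[0, 0])
            raise StructuralInconsistencyError(f"non-finite coordinate in conformer {bad}")
        if self.labels is not None and len(self.labels) != m:
            raise StructuralInconsistencyError("labels length must equal conformer count")

    # -- convenience views ---------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return self.elements != "H"

    def conformer(self, i: int) -> np.ndarray:
        """Coordinates of conformer ``i`` as an ``(N, 3)`` array (a view)."""
        return self.coords[i]

    def molecular_mass(self) -> float:
        """Total mass in unified atomic mass units."""
        return float(sum(ATOMIC_MASSES[a.element] for a in self.atoms))

    def with_charges(self, charges: Mapping[int, float]) -> "ConformerEnsemble":
        """Return a copy with partial charges replaced from an index->charge map.

        Every atom index must be covered (raises CoverageError otherwise).
        """
        missing = [a.atom_index for a in self.atoms if a.atom_index not in charges]
        if missing:
            raise CoverageError(
                f"charge table does not cover atom indices {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        atoms = [
            AtomRecord(a.atom_index, a.element, a.atom_name, a.residue_index,
                       a.residue_name, float(charges[a.atom_index]), a.radius_override)
            for a in self.atoms
        ]
        return ConformerEnsemble(atoms, self.coords.copy(), list(self.labels) if self.labels else None)


@dataclass
class ResidueAnnotation:
    """Map residue index -> structural-unit label.

    Labels are restricted to :data:`UNIT_LABELS` (core chitobiose, the
    two mannose arms, core fucose, and the reducing-end PA tag).
    """

    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, label in self.mapping.items():
            if label not in UNIT_LABELS:
                raise AnnotationError(
                    f"residue {res}: unknown unit label {label!r}; allowed: {UNIT_LABELS}"
                )

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, str] | Mapping[tuple[int, int], str]) -> "ResidueAnnotation":
        """Build from a {range: label} mapping; ranges are '3-5', '4', or (3, 5).

        Overlapping ranges raise :class:`AnnotationError`.
        """
        mapping: dict[int, str] = {}
        for key, label in ranges.items():
            if isinstance(key, tuple):
                lo, hi = key
            else:
                text = str(key).strip()
                if "-" in text[1:]:  # allow a single leading minus to fail naturally
                    lo_s, hi_s = text.split("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(text)
            if hi < lo:
                raise AnnotationError(f"empty residue range {key!r}")
            for res in range(lo, hi + 1):
                if res in mapping:
                    raise AnnotationError(
                        f"residue {res} assigned to both {mapping[res]!r} and {label!r}"
                    )
                mapping[res] = str(label)
        return cls(mapping)

    def label(self, residue_index: int) -> str:
        try:
            return self.mapping[residue_index]
        except KeyError:
            raise CoverageError(f"residue {residue_index} has no unit annotation") from None

    def validate_against(self, ensemble: ConformerEnsemble) -> None:
        """Check every residue present in the ensemble is labeled exactly once."""
        present = set(int(r) for r in ensemble.residue_indices)
        missing = sorted(present - set(self.mapping))
        if missing:
            raise CoverageError(f"annotation misses residues {missing}")

    def residues_with(self, label: str) -> list[int]:
        return sorted(r for r, lab in self.mapping.items() if lab == label)
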