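"""Reading and writing conformer ensembles and their sidecar tables.

Supported structure formats are the two plain-text ensemble carriers
used for gas-phase work: multi-model PDB (MODEL/ENDMDL blocks) and
concatenated XYZ (repeated ``N / comment / N atom lines`` frames).
Neither carries partial charges, so charges travel in a two-column
sidecar table, and residue -> structural-unit annotations in a small
key-value config file.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ensemble import (
    KNOWN_ELEMENTS,
    AtomRecord,
    ConformerEnsemble,
    ResidueAnnotation,
    normalize_element,
)
from .errors import CoverageError, ParseError, StructuralInconsistencyError

logger = logging.getLogger(__name__)

FORMATS = ("pdb-multimodel", "xyz-concatenated")

# Two-letter element symbols that can appear as the first two characters
# of a PDB atom name; everything else falls back to the first letter.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "FE", "ZN", "SE", "CA"}


def _element_from_atom_name(name: str) -> str:
    """Heuristic element inference when the PDB element column is blank.

    Strips digits/primes, then tries a two-letter symbol before the
    single-letter fallback.  Columns 13-16 conventions (e.g. '1HB')
    are handled by dropping leading digits.
    """
    stripped = re.sub(r"[0-9'\"]", "", name).strip().upper()
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb(text: str) -> tuple[list[AtomRecord], np.ndarray]:
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    seen_model_record = "MODEL" in text
    inferred_warned = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise ParseError(f"line {lineno}: ENDMDL without MODEL")
            models.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if seen_model_record and models:
                    raise ParseError(f"line {lineno}: ATOM record outside MODEL block")
                current = []
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip() or "UNK"
                resseq = int(line[22:26])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
            elem_col = line[76:78].strip() if len(line) >= 77 else ""
            if elem_col:
                element = normalize_element(elem_col)
            else:
                element = _element_from_atom_name(name)
                if not inferred_warned:
                    logger.warning("PDB lacks element columns; inferring elements from atom names")
                    inferred_warned = True
            if element not in KNOWN_ELEMENTS:
                raise ParseError(f"line {lineno}: unknown element symbol {element!r}")
            current.append((name, resseq, resname, element, x, y, z))
    if current:  # single-model file without MODEL/ENDMDL markers
        models.append(current)
    if not models:
        raise ParseError("no ATOM records found in PDB file")

    n0 = len(models[0])
    for i, model in enumerate(models):
        if len(model) != n0:
            raise StructuralInconsistencyError(
                f"model {i} has {len(model)} atoms; model 0 has {n0}"
            )
    atoms = [
        AtomRecord(atom_index=j, element=rec[3], atom_name=rec[0],
                   residue_index=rec[1], residue_name=rec[2])
        for j, rec in enumerate(models[0])
    ]
    coords = np.array([[rec[4:7] for rec in model] for model in models], dtype=float)
    return atoms, coords


def _write_pdb(ensemble: ConformerEnsemble, path: Path) -> None:
    lines: list[str] = []
    for m in range(ensemble.n_conformers):
        lines.append(f"MODEL     {m + 1:4d}")
        for a, (x, y, z) in zip(ensemble.atoms, ensemble.coords[m]):
            serial = a.atom_index + 1  # PDB serials are 1-based
            name = a.atom_name or a.element
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            elem = a.element.rjust(2)
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{a.residue_name:<3s} A"
                f"{a.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _parse_xyz(text: str) -> tuple[list[AtomRecord], np.ndarray]:
    lines = text.splitlines()
    frames: list[list[tuple]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise StructuralInconsistencyError(
                f"frame {len(frames)}: truncated (declares {n} atoms)"
            )
        frame = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise StructuralInconsistencyError(
                    f"frame {len(frames)}: atom line {k} is short: {lines[i + 2 + k]!r}"
                )
            element = normalize_element(parts[0])
            if element not in KNOWN_ELEMENTS:
                raise ParseError(f"frame {len(frames)}: unknown element {parts[0]!r}")
            try:
                xyz = tuple(float(p) for p in parts[1:4])
            except ValueError as exc:
                raise ParseError(f"frame {len(frames)}: bad coordinate: {exc}") from exc
            frame.append((element, *xyz))
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise ParseError("no frames found in XYZ file")
    n0 = len(frames[0])
    for j, frame in enumerate(frames):
        if len(frame) != n0:
            raise StructuralInconsistencyError(f"frame {j} has {len(frame)} atoms; frame 0 has {n0}")
        for k in range(n0):
            if frame[k][0] != frames[0][k][0]:
                raise StructuralInconsistencyError(
                    f"frame {j}: element order differs from frame 0 at atom {k}"
                )
    atoms = [AtomRecord(atom_index=k, element=frames[0][k][0], atom_name=frames[0][k][0])
             for k in range(n0)]
    coords = np.array([[rec[1:4] for rec in frame] for frame in frames], dtype=float)
    return atoms, coords


def _write_xyz(ensemble: ConformerEnsemble, path: Path) -> None:
    lines: list[str] = []
    for m in range(ensemble.n_conformers):
        lines.append(str(ensemble.n_atoms))
        lines.append(f"frame {m}")
        for a, (x, y, z) in zip(ensemble.atoms, ensemble.coords[m]):
            lines.append(f"{a.element.capitalize():<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_ensemble(path: str | Path, format: str | None = None) -> ConformerEnsemble:
    """Read a conformer ensemble from a multi-model PDB or concatenated XYZ file.

    ``format`` is one of ``'pdb-multimodel'`` / ``'xyz-concatenated'``;
    when omitted it is taken from the file suffix (.pdb / .xyz).
    """
    path = Path(path)
    if format is None:
        format = {"pdb": "pdb-multimodel", "xyz": "xyz-concatenated"}.get(
            path.suffix.lstrip(".").lower(), "")
    if format not in FORMATS:
        raise ParseError(f"unknown ensemble format {format!r}; expected one of {FORMATS}")
    text = path.read_text()
    atoms, coords = _parse_pdb(text) if format == "pdb-multimodel" else _parse_xyz(text)
    return ConformerEnsemble(atoms, coords)


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path, format: str | None = None) -> None:
    """Write an ensemble so that :func:`read_ensemble` recovers identical topology."""
    path = Path(path)
    if ensemble.n_conformers < 1:  # pragma: no cover - container forbids M=0
        raise StructuralInconsistencyError("refusing to write an empty ensemble")
    if format is None:
        format = {"pdb": "pdb-multimodel", "xyz": "xyz-concatenated"}.get(
            path.suffix.lstrip(".").lower(), "")
    if format not in FORMATS:
        raise ParseError(f"unknown ensemble format {format!r}; expected one of {FORMATS}")
    if format == "pdb-multimodel":
        _write_pdb(ensemble, path)
    else:
        _write_xyz(ensemble, path)


def read_charge_table(path: str | Path) -> dict[int, float]:
    """Read a two-column (atom index, partial charge) sidecar table.

    Whitespace- or comma-delimited; '#' comments allowed.  Indices are
    0-based.  Returns a plain dict; merge onto an ensemble with
    :meth:`ConformerEnsemble.with_charges`, which enforces coverage.
    """
    try:
        df = pd.read_csv(path, sep=r"[\s,]+", engine="python", comment="#", header=None)
    except Exception as exc:
        raise ParseError(f"cannot parse charge table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"charge table {path} must have two columns (index, charge)")
    # tolerate a header row
    if not np.issubdtype(df.dtypes[0], np.number):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        idx = df.iloc[:, 0].astype(int).to_numpy()
        q = df.iloc[:, 1].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric entry in charge table {path}: {exc}") from exc
    if not np.all(np.isfinite(q)):
        raise ParseError(f"non-finite charge in table {path}")
    if len(set(idx)) != len(idx):
        raise ParseError(f"duplicate atom index in charge table {path}")
    return {int(i): float(c) for i, c in zip(idx, q)}


def read_residue_annotation(path: str | Path) -> ResidueAnnotation:
    """Read a residue-range -> unit-label config (YAML mapping).

    Example::

        1-2: core-chitobiose
        3-5: alpha1-3-arm
        6-8: alpha1-6-arm
    """
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse annotation file {path}: {exc}") from exc
    if not isinstance(data, Mapping) or not data:
        raise ParseError(f"annotation file {path} must be a non-empty mapping")
    return ResidueAnnotation.from_ranges({str(k): str(v) for k, v in data.items()})


def write_residue_annotation(annotation: ResidueAnnotation, path: str | Path) -> None:
    """Write an annotation as a run-length-compressed range -> label mapping."""
    runs: list[list] = []
    for res, lab in sorted(annotation.mapping.items()):
        if runs and runs[-1][2] == lab and res == runs[-1][1] + 1:
            runs[-1][1] = res
        else:
            runs.append([res, res, lab])
    ranges = {(f"{a}-{b}" if b != a else f"{a}"): lab for a, b, lab in runs}
    Path(path).write_text(yaml.safe_dump(ranges, sort_keys=False))
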