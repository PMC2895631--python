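"""Atomistic structures: PDB I/O, radius assignment, residue harmonization, descriptors.

A structure is an ordered collection of atoms with coordinates in Å. Ensembles
(multi-model PDB files or lists of conformations) represent the conformational
spread of one state (open or closed) of a protein. All geometric descriptors
(radius of gyration, selection centre-of-mass distances) are mass-weighted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "AtomisticStructure",
    "ConformationalEnsemble",
    "BONDI_RADII",
    "ATOMIC_MASSES",
    "PDBParseError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "assign_radii",
    "common_residue_filter",
    "radius_of_gyration",
    "selection_com_distance",
]

#: Bondi van der Waals radii (Å); the default hard-core radius set.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NE": 1.54, "NA": 2.27, "MG": 1.73, "SI": 2.10, "P": 1.80, "S": 1.80,
    "CL": 1.75, "AR": 1.88, "K": 2.75, "CA": 2.31, "ZN": 1.39, "CU": 1.40,
    "FE": 2.00, "MN": 2.00, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "HE": 4.003, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NE": 20.180, "NA": 22.990, "MG": 24.305, "SI": 28.085,
    "P": 30.974, "S": 32.06, "CL": 35.45, "AR": 39.948, "K": 39.098,
    "CA": 40.078, "MN": 54.938, "FE": 55.845, "CU": 63.546, "ZN": 65.38,
    "SE": 78.971, "BR": 79.904, "I": 126.904,
}

_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL", "DOD"}


class PDBParseError(ValueError):
    """Raised when PDB-format text cannot be parsed into a structure."""


@dataclass(frozen=True)
class Atom:
    """One atom: element, position (Å), hard-core radius (Å), mass (amu)."""

    element: str
    coords: np.ndarray
    radius: float
    mass: float
    residue_id: tuple[str, int, str]  # (chain, residue number, residue name)
    atom_name: str


@dataclass
class AtomisticStructure:
    """One conformation, stored as parallel per-atom arrays (file order).

    ``radii`` is NaN until :func:`assign_radii` has been applied; operations
    needing hard-core radii check this.
    """

    elements: np.ndarray          # (n,) str
    coords: np.ndarray            # (n, 3) float, Å
    radii: np.ndarray             # (n,) float, Å; NaN if unassigned
    masses: np.ndarray            # (n,) float, amu
    chain_ids: np.ndarray         # (n,) str
    res_ids: np.ndarray           # (n,) int
    res_names: np.ndarray         # (n,) str
    atom_names: np.ndarray        # (n,) str
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def has_radii(self) -> bool:
        return len(self) > 0 and bool(np.all(np.isfinite(self.radii)))

    @property
    def residue_ids(self) -> list[tuple[str, int, str]]:
        return [
            (str(c), int(i), str(n))
            for c, i, n in zip(self.chain_ids, self.res_ids, self.res_names)
        ]

    @property
    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                element=str(self.elements[i]),
                coords=self.coords[i].copy(),
                radius=float(self.radii[i]),
                mass=float(self.masses[i]),
                residue_id=(str(self.chain_ids[i]), int(self.res_ids[i]),
                            str(self.res_names[i])),
                atom_name=str(self.atom_names[i]),
            )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "AtomisticStructure":
        return AtomisticStructure(
            elements=self.elements[mask],
            coords=self.coords[mask],
            radii=self.radii[mask],
            masses=self.masses[mask],
            chain_ids=self.chain_ids[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            label=self.label if label is None else label,
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "AtomisticStructure":
        out = replace(self)
        out.coords = np.array(coords, dtype=float)
        out.radii = self.radii.copy()
        if label is not None:
            out.label = label
        return out


@dataclass
class ConformationalEnsemble:
    """Conformations of one state; all must share atom count and ordering."""

    conformations: list[AtomisticStructure]
    state_label: str = ""

    def __post_init__(self) -> None:
        if self.conformations:
            n0 = self.conformations[0].n_atoms
            names0 = self.conformations[0].atom_names
            for c in self.conformations[1:]:
                if c.n_atoms != n0 or not np.array_equal(c.atom_names, names0):
                    raise ValueError(
                        "all conformations must share atom count and ordering"
                    )

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[AtomisticStructure]:
        return iter(self.conformations)


def _from_atom_array(arr: "struc.AtomArray", label: str) -> AtomisticStructure:
    n = arr.array_length()
    elements = np.array([e.upper() for e in arr.element], dtype=object)
    masses = np.array([ATOMIC_MASSES.get(e, np.nan) for e in elements])
    return AtomisticStructure(
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
        radii=np.full(n, np.nan),
        masses=masses,
        chain_ids=np.array([str(c) for c in arr.chain_id], dtype=object),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=np.array([str(r) for r in arr.res_name], dtype=object),
        atom_names=np.array([str(a) for a in arr.atom_name], dtype=object),
        label=label,
    )


def read_structure(
    pdb_text: str,
    model_index: int = 1,
    include_hetero: bool = False,
    include_water: bool = False,
    label: str = "",
) -> AtomisticStructure:
    """Parse one model from PDB-format text.

    ``model_index`` is 1-based, following the MODEL record convention.
    Waters and (by default) other heteroatoms are excluded.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if n_models == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    if not 1 <= model_index <= n_models:
        raise PDBParseError(
            f"model_index {model_index} out of range (file has {n_models} models)"
        )
    try:
        arr = pdb.get_structure(model=model_index)
    except Exception as exc:
        raise PDBParseError(f"malformed coordinate record: {exc}") from exc
    mask = np.ones(arr.array_length(), dtype=bool)
    water = np.isin(arr.res_name, list(_WATER_NAMES))
    if not include_water:
        mask &= ~water
    if not include_hetero:
        mask &= ~(arr.hetero & ~water)
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBParseError("no atoms remain after filtering")
    return _from_atom_array(arr, label)


def read_ensemble(
    pdb_text: str,
    state_label: str = "",
    include_hetero: bool = False,
) -> ConformationalEnsemble:
    """Read all models of a multi-model PDB file as one ensemble."""
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    confs = [
        read_structure(pdb_text, model_index=m, include_hetero=include_hetero,
                       label=f"{state_label}[{m}]")
        for m in range(1, n_models + 1)
    ]
    return ConformationalEnsemble(confs, state_label=state_label)


def _to_atom_array(s: AtomisticStructure) -> "struc.AtomArray":
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = np.array([c[:4] for c in s.chain_ids], dtype="U4")
    arr.res_id = np.asarray(s.res_ids, dtype=int)
    arr.res_name = np.array([r[:5] for r in s.res_names], dtype="U5")
    arr.atom_name = np.array([a[:6] for a in s.atom_names], dtype="U6")
    arr.element = np.array([e[:2] for e in s.elements], dtype="U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_structure(structure: AtomisticStructure) -> str:
    """Serialize one conformation to PDB-format text."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def write_ensemble(ensemble: ConformationalEnsemble) -> str:
    """Serialize an ensemble to multi-model PDB text."""
    arrays = [_to_atom_array(c) for c in ensemble]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    out = io.StringIO()
    pdb.write(out)
    return out.getvalue()


def assign_radii(
    structure: AtomisticStructure,
    radius_set: dict[str, float] | None = None,
    strip_hydrogens: bool = False,
) -> AtomisticStructure:
    """Assign per-atom hard-core radii from an element table (default Bondi).

    Raises ``KeyError`` naming any element absent from the table.
    """
    table = {k.upper(): v for k, v in (radius_set or BONDI_RADII).items()}
    s = structure
    if strip_hydrogens:
        s = s.subset(s.elements != "H")
    missing = sorted({e for e in s.elements if e not in table})
    if missing:
        raise KeyError(
            f"no radius for element(s): {', '.join(missing)}"
        )
    radii = np.array([table[e] for e in s.elements], dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii in the radius set must be > 0")
    out = s.subset(np.ones(len(s), dtype=bool))
    out.radii = radii
    return out


def common_residue_filter(
    open_s: AtomisticStructure, closed_s: AtomisticStructure
) -> tuple[AtomisticStructure, AtomisticStructure]:
    """Keep only residues present in both conformations.

    Residues are matched on (chain, residue number, residue name); relative
    atom order is preserved. Removes the artificial free-energy contribution
    that residues present in only one end-state would otherwise make.
    """

    def keys(s: AtomisticStructure) -> list[tuple[str, int, str]]:
        return s.residue_ids

    open_keys = keys(open_s)
    closed_keys = keys(closed_s)
    common = set(open_keys) & set(closed_keys)
    if not common:
        raise ValueError("open and closed structures share no residues")
    open_mask = np.array([k in common for k in open_keys])
    closed_mask = np.array([k in common for k in closed_keys])
    return open_s.subset(open_mask), closed_s.subset(closed_mask)


def radius_of_gyration(structure: AtomisticStructure) -> float:
    """Mass-weighted radius of gyration (Å)."""
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    m = structure.masses
    if not np.all(np.isfinite(m)) or np.sum(m) <= 0:
        raise ValueError("all atoms need positive masses")
    com = np.average(structure.coords, axis=0, weights=m)
    d2 = np.sum((structure.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def _range_mask(
    s: AtomisticStructure, sel: tuple[int, int] | tuple[str, int, int]
) -> np.ndarray:
    if len(sel) == 3:
        chain, lo, hi = sel
        mask = (s.chain_ids == chain) & (s.res_ids >= lo) & (s.res_ids <= hi)
    else:
        lo, hi = sel
        mask = (s.res_ids >= lo) & (s.res_ids <= hi)
    return mask


def selection_com_distance(
    structure: AtomisticStructure,
    sel_a: tuple[int, int] | tuple[str, int, int],
    sel_b: tuple[int, int] | tuple[str, int, int],
) -> float:
    """Distance between mass-weighted centroids of two residue ranges (Å).

    A selection is ``(first_res, last_res)`` (inclusive) or
    ``(chain, first_res, last_res)``.
    """
    coms = []
    for name, sel in (("sel_a", sel_a), ("sel_b", sel_b)):
        mask = _range_mask(structure, sel)
        if not np.any(mask):
            raise ValueError(f"selection {name}={sel} matches no atoms")
        sub = structure.subset(mask)
        coms.append(np.average(sub.coords, axis=0, weights=sub.masses))
    return float(np.linalg.norm(coms[0] - coms[1]))
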