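"""Protein structure handling and active-site layer analysis.

An enzyme's active site can be organized into shells around the bound
substrate: *first-layer* residues are in direct contact with the ligand,
*second-layer* residues lie within a shell cutoff of a first-layer residue,
and *third-layer* residues within the same cutoff of a second-layer residue.
This module parses PDB text, resolves alternate conformers, computes
heavy-atom distances, and assigns those shell labels deterministically.

Distances are minimum heavy-atom (non-hydrogen) Euclidean distances in Å.
Residues are identified per (chain, residue number); contacts across chains
count toward shells, because trimeric active sites sit at subunit interfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "LigandMoiety",
    "LayerAssignment",
    "StructureFormatError",
    "RecordError",
    "read_structure",
    "min_heavy_atom_distance",
    "first_layer",
    "assign_layers",
    "distance_report",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

# heavy-atom counts of complete standard residues, used only to warn about
# severely incomplete side chains (no repair is attempted)
_EXPECTED_HEAVY = {
    "GLY": 4, "ALA": 5, "SER": 6, "CYS": 6, "THR": 7, "VAL": 7, "PRO": 7,
    "LEU": 8, "ILE": 8, "ASN": 8, "ASP": 8, "MET": 8, "GLN": 9, "GLU": 9,
    "LYS": 9, "HIS": 10, "ARG": 11, "PHE": 11, "TYR": 12, "TRP": 14,
}


class StructureFormatError(ValueError):
    """No parsable ATOM/HETATM records in the input."""


class RecordError(ValueError):
    """A single malformed record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_num: int
    chain: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False
    mass: float = 0.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain, self.res_num)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """A flat list of atoms with cached per-residue indexing."""

    atoms: list[Atom]
    _residue_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValueError(f"atom {a.serial} {a.name} has non-finite coordinates")
        self._rebuild_index()

    def _rebuild_index(self):
        idx: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            idx.setdefault(a.residue_id, []).append(i)
        self._residue_index = idx

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def residue_ids(self, het: bool | None = False) -> list[tuple[str, int]]:
        """Residue ids in order of first appearance.

        het=False → protein residues only, het=True → ligand/het residues,
        het=None → all.
        """
        seen, out = set(), []
        for a in self.atoms:
            if het is not None and a.het != het:
                continue
            if a.residue_id not in seen:
                seen.add(a.residue_id)
                out.append(a.residue_id)
        return out

    def residue_atoms(self, residue_id: tuple[str, int]) -> list[Atom]:
        try:
            return [self.atoms[i] for i in self._residue_index[residue_id]]
        except KeyError:
            raise KeyError(f"residue {residue_id[0]}:{residue_id[1]} not in structure") from None

    def residue_name(self, residue_id: tuple[str, int]) -> str:
        return self.residue_atoms(residue_id)[0].res_name

    def het_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.het]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.het]


@dataclass
class LigandMoiety:
    """A labelled subset of het atoms, e.g. the CP-like or ORN-like part of
    a bound bisubstrate analog."""

    label: str
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"moiety {self.label!r} has no atoms")
        non_het = [a.name for a in self.atoms if not a.het]
        if non_het:
            raise ValueError(f"moiety {self.label!r} contains non-het atoms: {non_het}")


@dataclass
class LayerAssignment:
    """Per-residue shell labels plus min heavy-atom distance to each moiety.

    ``layers`` maps residue id -> 1 | 2 | 3 | None; ``distances`` maps moiety
    label -> {residue id -> Å}.
    """

    layers: dict[tuple[str, int], int | None]
    distances: dict[str, dict[tuple[str, int], float]]
    residue_names: dict[tuple[str, int], str]
    shell_cutoff: float
    contact_cutoff: float

    def in_layer(self, n: int) -> set[tuple[str, int]]:
        return {rid for rid, lab in self.layers.items() if lab == n}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, lab in self.layers.items():
            row = {
                "chain": rid[0],
                "res_num": rid[1],
                "res_name": self.residue_names[rid],
                "layer": lab if lab is not None else "none",
            }
            for moiety, dmap in self.distances.items():
                row[f"dist_{moiety}"] = dmap[rid]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parsing


def _validate_records(pdb_text: str) -> int:
    """Scan ATOM/HETATM lines, raising RecordError on malformed coordinates.

    Returns the number of coordinate records seen.
    """
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise RecordError(lineno, "record too short for coordinates")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise RecordError(lineno, f"malformed {what} coordinate field {line[lo:hi]!r}") from None
    return n


def read_structure(
    pdb_text: str,
    chain: str | None = None,
    drop_waters: bool = True,
    model: int = 0,
) -> Structure:
    """Parse PDB-format text into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by alphabetically first altloc id). Waters (HOH) are
    dropped by default. Only the requested model of a multi-model file is
    read. Residues missing more than half their expected heavy atoms
    trigger a warning; no repair is attempted.
    """
    if _validate_records(pdb_text) == 0:
        raise StructureFormatError("no ATOM or HETATM records found")
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    gmodel = st[model]

    raw: list[Atom] = []
    for gchain in gmodel:
        if chain is not None and gchain.name != chain:
            continue
        for res in gchain:
            het = res.het_flag == "H"
            if drop_waters and res.name.strip() in WATER_NAMES:
                continue
            for at in res:
                el = at.element.name
                raw.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=el,
                        res_name=res.name.strip(),
                        res_num=res.seqid.num,
                        chain=gchain.name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=at.occ,
                        altloc=at.altloc.strip() if at.altloc else "",
                        het=het,
                        mass=at.element.weight,
                    )
                )
    if not raw:
        raise StructureFormatError(
            "no atoms retained" + (f" for chain {chain!r}" if chain else "")
        )

    # altloc resolution: keep highest occupancy, tie -> first altloc id
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in raw:
        key = (a.chain, a.res_num, a.res_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy > b.occupancy) or (
                a.occupancy == b.occupancy and a.altloc < b.altloc
            ):
                best[key] = a
    structure = Structure([best[k] for k in order])
    _warn_incomplete(structure)
    return structure


def _warn_incomplete(structure: Structure) -> None:
    bad = []
    for rid in structure.residue_ids(het=False):
        atoms = structure.residue_atoms(rid)
        name = atoms[0].res_name
        expected = _EXPECTED_HEAVY.get(name)
        if expected is None:
            continue
        n_heavy = sum(1 for a in atoms if not a.is_hydrogen)
        if n_heavy < 0.5 * expected:
            bad.append(f"{name}{rid[1]}:{rid[0]}")
    if bad:
        warnings.warn(
            f"{len(bad)} residue(s) have <50% of expected heavy atoms: {', '.join(bad)}",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# distances and layers


def _heavy_coords(atoms: Iterable[Atom]) -> np.ndarray:
    pts = [[a.x, a.y, a.z] for a in atoms if not a.is_hydrogen]
    return np.asarray(pts, dtype=float)


def min_heavy_atom_distance(a: Sequence[Atom], b: Sequence[Atom]) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom cross pairs."""
    pa, pb = _heavy_coords(a), _heavy_coords(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("both atom sets must contain at least one heavy atom")
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def first_layer(
    structure: Structure,
    ligand: LigandMoiety,
    contact_cutoff: float = 4.0,
) -> set[tuple[str, int]]:
    """Residues in direct substrate contact.

    A residue is first-layer if its minimum heavy-atom distance to the
    ligand moiety is <= ``contact_cutoff`` (Å). The default 4.0 Å contact
    rule is a deterministic distance-based stand-in for surface
    complementarity contact detection.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    lig = _heavy_coords(ligand.atoms)
    if lig.size == 0:
        raise ValueError("ligand moiety has no heavy atoms")
    out = set()
    for rid in structure.residue_ids(het=False):
        if min_heavy_atom_distance(structure.residue_atoms(rid), ligand.atoms) <= contact_cutoff:
            out.add(rid)
    return out


def _residue_min_dist(structure: Structure, rid_a, rid_b) -> float:
    return min_heavy_atom_distance(
        structure.residue_atoms(rid_a), structure.residue_atoms(rid_b)
    )


def assign_layers(
    structure: Structure,
    first: set[tuple[str, int]],
    shell_cutoff: float = 5.0,
    moieties: Sequence[LigandMoiety] = (),
    contact_cutoff: float = 4.0,
) -> LayerAssignment:
    """Assign 1st/2nd/3rd shell labels around a given first layer.

    Second-layer residues are within ``shell_cutoff`` Å (min heavy-atom
    distance, whole residue) of at least one first-layer residue and are not
    themselves first-layer; third-layer residues likewise relative to the
    second layer. A residue eligible for several shells gets the lowest
    shell number. Everything else is labelled None.
    """
    if not first:
        raise ValueError("first layer is empty")
    residues = structure.residue_ids(het=False)
    missing = [r for r in first if r not in set(residues)]
    if missing:
        raise KeyError(f"first-layer residues not in structure: {missing}")

    layers: dict[tuple[str, int], int | None] = {rid: None for rid in residues}
    for rid in first:
        layers[rid] = 1

    def grow(source_layer: int) -> set:
        sources = [rid for rid, lab in layers.items() if lab == source_layer]
        added = set()
        for rid in residues:
            if layers[rid] is not None:
                continue
            for s in sources:
                if _residue_min_dist(structure, rid, s) <= shell_cutoff:
                    added.add(rid)
                    break
        return added

    for rid in grow(1):
        layers[rid] = 2
    for rid in grow(2):
        layers[rid] = 3

    distances: dict[str, dict] = {}
    for m in moieties:
        distances[m.label] = {
            rid: min_heavy_atom_distance(structure.residue_atoms(rid), m.atoms)
            for rid in residues
        }
    names = {rid: structure.residue_name(rid) for rid in residues}
    return LayerAssignment(
        layers=layers,
        distances=distances,
        residue_names=names,
        shell_cutoff=shell_cutoff,
        contact_cutoff=contact_cutoff,
    )


def distance_report(
    assignment: LayerAssignment,
    residues: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Tabulate, per residue, its layer and the distance to the nearest
    ligand moiety (and which moiety that is).

    ``residues`` defaults to every residue assigned to a shell. Raises
    KeyError naming the residue if one is absent from the assignment.
    """
    if not assignment.distances:
        raise ValueError("assignment carries no moiety distances")
    if residues is None:
        residues = [rid for rid, lab in assignment.layers.items() if lab is not None]
    rows = []
    for rid in residues:
        if rid not in assignment.layers:
            raise KeyError(f"residue {rid[0]}:{rid[1]} not in layer assignment")
        dists = {m: assignment.distances[m][rid] for m in assignment.distances}
        nearest = min(dists, key=dists.get)
        rows.append(
            {
                "chain": rid[0],
                "res_num": rid[1],
                "res_name": assignment.residue_names[rid],
                "layer": assignment.layers[rid] or "none",
                "distance": dists[nearest],
                "moiety": nearest,
            }
        )
    return pd.DataFrame(rows)
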