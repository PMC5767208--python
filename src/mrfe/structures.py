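"""Structure I/O, chemical feature channels and rigid-body superposition.

Atoms are typed into five feature channels used by the voxelizer:

======= ==========================================
channel meaning
======= ==========================================
0       polar hydrogens (hydrogen-bond donors)
1       hydrophobic atoms (C, Cl, Br, I)
2       nitrogen (hydrogen-bond acceptor, type 1)
3       oxygen / fluorine (acceptor, type 2)
4       d-elements (S, P)
======= ==========================================

Ligand atoms carry sign −1, receptor atoms +1, so the two molecules are
contrasted inside one signed density map.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "MolecularComplex",
    "RadiiTable",
    "ChannelAssignment",
    "LigandSelector",
    "DEFAULT_RADII",
    "StructureFormatError",
    "RadiiLookupError",
    "DegenerateGeometryError",
    "assign_channel",
    "read_structure",
    "write_structure",
    "superpose",
]

LIGAND = "ligand"
RECEPTOR = "receptor"

#: Bondi-style van-der-Waals radii and Shannon-style ionic radii (Å) for the
#: ten elements that populate the five feature channels.  User-overridable.
DEFAULT_RADII: dict[str, tuple[float, float]] = {
    "H": (0.25, 1.20),
    "C": (0.70, 1.70),
    "N": (0.65, 1.55),
    "O": (0.60, 1.52),
    "F": (0.50, 1.47),
    "P": (1.00, 1.80),
    "S": (1.00, 1.80),
    "Cl": (0.99, 1.75),
    "Br": (1.14, 1.85),
    "I": (1.33, 1.98),
}

#: Residue names never treated as ligand by the default selector.
_SOLVENT_IONS = {"HOH", "WAT", "TIP", "TIP3", "SOL", "NA", "CL", "K", "MG", "CA", "ZN"}

#: Elements whose proximity makes a hydrogen "polar" (donor-capable).
_POLAR_NEIGHBOURS = {"N", "O", "S"}

#: Hydrogen–heteroatom distance below which an H counts as polar (Å).
POLAR_H_CUTOFF = 1.2


class StructureFormatError(ValueError):
    """Raised when PDB text cannot be parsed; names the offending line."""


class RadiiLookupError(KeyError):
    """Raised when an element has no entry in the radii table."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # KeyError quotes its arg; keep a sentence
        return f"element {self.element!r} has no entry in the radii table"


class DegenerateGeometryError(ValueError):
    """Raised when superposition anchors are too few or collinear."""


class RadiiTable:
    """Per-element (ionic, van-der-Waals) radii in Å.

    JSON form: ``{"C": [0.70, 1.70], ...}``.
    """

    def __init__(self, radii: Optional[dict[str, tuple[float, float]]] = None):
        self._radii = {k: (float(v[0]), float(v[1])) for k, v in (radii or DEFAULT_RADII).items()}
        for el, (r_ion, r_vdw) in self._radii.items():
            if not (0.0 < r_ion < r_vdw):
                raise ValueError(f"invalid radii for {el}: r_ion={r_ion}, r_vdw={r_vdw}")

    def __contains__(self, element: str) -> bool:
        return element in self._radii

    def lookup(self, element: str) -> tuple[float, float]:
        try:
            return self._radii[element]
        except KeyError:
            raise RadiiLookupError(element) from None

    def elements(self) -> list[str]:
        return sorted(self._radii)

    @classmethod
    def from_json(cls, text: str) -> "RadiiTable":
        return cls({k: tuple(v) for k, v in json.loads(text).items()})

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self._radii.items()}, indent=1)


@dataclass
class Atom:
    """One typed atom: element, Cartesian coordinates (Å), ownership, radii."""

    element: str
    coords: np.ndarray
    owner: str  # LIGAND or RECEPTOR
    is_polar_hydrogen: bool = False
    r_ion: float = 0.0
    r_vdw: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if self.owner not in (LIGAND, RECEPTOR):
            raise ValueError(f"owner must be {LIGAND!r} or {RECEPTOR!r}")
        if self.r_ion <= 0 or self.r_vdw <= self.r_ion:
            raise ValueError("require 0 < r_ion < r_vdw")


@dataclass
class MolecularComplex:
    """An ordered set of atoms forming one protein–ligand complex."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self):
        if not any(a.owner == LIGAND for a in self.atoms):
            raise ValueError("complex must contain at least one ligand atom")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in complex")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.owner == LIGAND]

    @property
    def receptor_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.owner == RECEPTOR]

    @property
    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float)

    def ligand_centroid(self) -> np.ndarray:
        return self.ligand_coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, label: Optional[str] = None) -> "MolecularComplex":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.element, c, a.owner, a.is_polar_hydrogen, a.r_ion, a.r_vdw)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularComplex(atoms, label if label is not None else self.label)

    def __len__(self) -> int:
        return len(self.atoms)


class ChannelAssignment(NamedTuple):
    channel: int  # 0..4, see module docstring
    sign: int  # −1 ligand, +1 receptor


_ELEMENT_CHANNEL = {
    "C": 1, "Cl": 1, "Br": 1, "I": 1,
    "N": 2,
    "O": 3, "F": 3,
    "S": 4, "P": 4,
}


def assign_channel(atom: Atom) -> Optional[ChannelAssignment]:
    """Map an atom onto one of the five feature channels.

    Returns ``None`` (the explicit no-channel sentinel) for atoms outside
    the five maps — notably nonpolar hydrogens — which contribute no
    density.
    """
    sign = -1 if atom.owner == LIGAND else +1
    if atom.element == "H":
        return ChannelAssignment(0, sign) if atom.is_polar_hydrogen else None
    ch = _ELEMENT_CHANNEL.get(atom.element)
    if ch is None:
        return None
    return ChannelAssignment(ch, sign)


@dataclass
class LigandSelector:
    """Rule deciding which atoms belong to the ligand.

    Default rule: HETATM records whose residue name is not solvent/ion.
    Explicit ``resnames`` / ``chains`` override the default; a custom
    ``predicate(res_name, chain_id, hetero) -> bool`` overrides everything.
    """

    resnames: Optional[frozenset[str]] = None
    chains: Optional[frozenset[str]] = None
    predicate: Optional[Callable[[str, str, bool], bool]] = None

    @classmethod
    def by_resname(cls, *names: str) -> "LigandSelector":
        return cls(resnames=frozenset(n.upper() for n in names))

    @classmethod
    def by_chain(cls, *chains: str) -> "LigandSelector":
        return cls(chains=frozenset(chains))

    def is_ligand(self, res_name: str, chain_id: str, hetero: bool) -> bool:
        if self.predicate is not None:
            return self.predicate(res_name, chain_id, hetero)
        if self.resnames is not None:
            return res_name.upper() in self.resnames
        if self.chains is not None:
            return chain_id in self.chains
        return hetero and res_name.upper() not in _SOLVENT_IONS


def _normalise_element(raw: str) -> str:
    raw = raw.strip()
    if not raw:
        return raw
    return raw[0].upper() + raw[1:].lower()


def _prescan_pdb(pdb_text: str) -> None:
    """Cheap structural validation producing line-numbered errors."""
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureFormatError(f"line {ln}: truncated ATOM/HETATM record")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError:
            raise StructureFormatError(
                f"line {ln}: unparseable coordinates in record {line[:27]!r}"
            ) from None


def read_structure(
    pdb_text: str,
    ligand_selector: Optional[LigandSelector] = None,
    radii: Optional[RadiiTable] = None,
    label: str = "",
) -> MolecularComplex:
    """Parse PDB text into a :class:`MolecularComplex`.

    ATOM/HETATM records are kept in file order; occupancy and B-factor are
    ignored.  Ownership follows ``ligand_selector`` (default: HETATM minus
    solvent/ions).  Radii come from ``radii`` (default table); an element
    missing from the table raises :class:`RadiiLookupError`.
    """
    import biotite.structure.io.pdb as pdb

    selector = ligand_selector or LigandSelector()
    table = radii or RadiiTable()
    _prescan_pdb(pdb_text)
    try:
        pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise StructureFormatError(f"PDB parse failure: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureFormatError("no ATOM/HETATM records found")

    elements = [_normalise_element(e) for e in arr.element]
    owners = [
        LIGAND if selector.is_ligand(rn, cid, bool(het)) else RECEPTOR
        for rn, cid, het in zip(arr.res_name, arr.chain_id, arr.hetero)
    ]
    coords = np.asarray(arr.coord, dtype=float)

    # Polar-hydrogen rule: H within POLAR_H_CUTOFF of N/O/S.
    hetero_mask = np.array([e in _POLAR_NEIGHBOURS for e in elements])
    polar = np.zeros(len(elements), dtype=bool)
    if hetero_mask.any():
        het_xyz = coords[hetero_mask]
        for i, e in enumerate(elements):
            if e == "H":
                d = np.linalg.norm(het_xyz - coords[i], axis=1)
                polar[i] = bool((d < POLAR_H_CUTOFF).any())

    atoms = []
    for i, e in enumerate(elements):
        r_ion, r_vdw = table.lookup(e)
        atoms.append(Atom(e, coords[i], owners[i], bool(polar[i]), r_ion, r_vdw))
    return MolecularComplex(atoms, label=label)


def write_structure(complex_: MolecularComplex) -> str:
    """Serialize a complex to PDB text (ligand as HETATM ``LIG``, receptor
    as ATOM ``REC``); round-trips elements and coordinates at PDB precision."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(complex_.atoms)
    arr = struc.AtomArray(n)
    arr.coord = complex_.coords.astype(np.float32)
    for i, a in enumerate(complex_.atoms):
        is_lig = a.owner == LIGAND
        arr.chain_id[i] = "L" if is_lig else "A"
        arr.res_id[i] = 1 if is_lig else 2
        arr.res_name[i] = "LIG" if is_lig else "REC"
        arr.hetero[i] = is_lig
        arr.atom_name[i] = f"{a.element.upper()}{i % 99 + 1}"
        arr.element[i] = a.element.upper()
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    return "\n".join(pdb_file.lines) + "\n"


def superpose(
    mobile: MolecularComplex,
    reference: MolecularComplex,
    anchor: Sequence[tuple[int, int]],
) -> tuple[MolecularComplex, float]:
    """Rigid-body least-squares superposition of ``mobile`` onto ``reference``.

    ``anchor`` pairs index (mobile_atom, reference_atom).  Returns the
    transformed complex and the anchor RMSD in Å.  Requires ≥3
    non-collinear anchor pairs (Kabsch needs a full-rank point cloud).
    """
    pairs = list(anchor)
    if len(pairs) < 3:
        raise DegenerateGeometryError("need at least 3 anchor pairs")
    mob_idx = [p[0] for p in pairs]
    ref_idx = [p[1] for p in pairs]
    mob = mobile.coords[mob_idx]
    ref = reference.coords[ref_idx]
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # Collinear anchors leave a rotational degree of freedom undetermined.
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("anchor atoms are collinear")

    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    new_coords = rot.apply(mobile.coords - mob.mean(axis=0)) + ref.mean(axis=0)
    moved = mobile.with_coords(new_coords)
    rmsd = float(np.sqrt(np.mean(np.sum((moved.coords[mob_idx] - ref) ** 2, axis=1))))
    return moved, rmsd


def ligand_rmsd(a: MolecularComplex, b: MolecularComplex) -> float:
    """Plain (no refit) RMSD between the ligand atoms of two complexes."""
    ca, cb = a.ligand_coords, b.ligand_coords
    if ca.shape != cb.shape:
        raise ValueError("ligand atom counts differ")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))
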