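"""Reading, validating and writing IMGT-numbered nanobody structures.

The input contract is that residue numbers in the coordinate file *are*
IMGT positions (with insertion codes), one VHH domain per file, as produced
by antibody structure predictors or by renumbering a crystal structure.
Under IMGT, the hypervariable loops occupy fixed spans: CDR1 27-38,
CDR2 56-65, CDR3 105-117; the FR2 "tetrad" hallmark positions are
42, 49, 50 and 52; the CDR3 anchors are 104 and 118.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping

import gemmi
import numpy as np

from .errors import (
    AmbiguityError,
    EmptyStructureError,
    ParseError,
)

Region = Literal["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}
_AA1TO3["X"] = "UNK"


@functools.total_ordering
@dataclass(frozen=True)
class ImgtId:
    """An IMGT position with an optional single-letter insertion code.

    Ordering is (position, insertion) with the empty insertion first and
    insertion codes compared alphabetically.  IMGT's bidirectional insertion
    convention inside the 111/112 block is deliberately simplified to plain
    alphabetical order: ordering only affects sequence display, never a
    metric (lengths count residues, geometry uses coordinates).
    """

    position: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"IMGT position must be >= 1, got {self.position}")
        ins = self.insertion.strip()
        if ins != self.insertion:
            object.__setattr__(self, "insertion", ins)
        if len(self.insertion) > 1 or (self.insertion and not self.insertion.isupper()):
            raise ValueError(f"insertion code must be one uppercase letter, got {self.insertion!r}")

    def __lt__(self, other: "ImgtId") -> bool:
        return (self.position, self.insertion) < (other.position, other.insertion)

    def __str__(self) -> str:
        return f"{self.position}{self.insertion}"

    @classmethod
    def parse(cls, text: str) -> "ImgtId":
        """Parse ``"112"`` or ``"111A"`` into an :class:`ImgtId`."""
        text = text.strip()
        num = text.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        return cls(int(num), text[len(num):])


@dataclass
class Residue:
    """One amino acid with heavy-atom coordinates (PDB atom naming)."""

    id: ImgtId
    aa: str
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.aa not in _AA1TO3:
            raise ValueError(f"unknown amino-acid code {self.aa!r}")
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        ca = self.atoms.get("CA")
        if ca is not None and not np.all(np.isfinite(ca)):
            raise ValueError(f"non-finite CA coordinates at {self.id}")

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def side_chain_atoms(self) -> dict[str, np.ndarray]:
        return {n: c for n, c in self.atoms.items() if n not in BACKBONE_ATOMS}


@dataclass
class RegionDefinition:
    """IMGT framework/CDR spans, CDR3 anchors and tetrad positions."""

    cdr1: tuple[int, int] = (27, 38)
    cdr2: tuple[int, int] = (56, 65)
    cdr3: tuple[int, int] = (105, 117)
    cdr3_anchors: tuple[int, int] = (104, 118)
    tetrad_positions: tuple[int, int, int, int] = (42, 49, 50, 52)

    def span(self, region: Region) -> tuple[int, int]:
        return {"CDR1": self.cdr1, "CDR2": self.cdr2, "CDR3": self.cdr3}[region]


IMGT_REGIONS = RegionDefinition()

#: Conserved positions whose absence suggests the file is not IMGT-numbered.
CONSERVED_CYSTEINES = (23, 104)


@dataclass
class NanobodyStructure:
    """An ordered, IMGT-numbered VHH domain (single chain)."""

    residues: list[Residue]
    source_id: str = ""
    regions: RegionDefinition = field(default_factory=RegionDefinition)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.residues]
        for a, b in zip(ids, ids[1:]):
            if not a < b:
                raise ValueError(f"residue ids not strictly increasing: {a} !< {b}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def get(self, id: ImgtId | int) -> Residue | None:
        if isinstance(id, int):
            id = ImgtId(id)
        return self._index().get(id)

    def _index(self) -> dict[ImgtId, Residue]:
        # rebuilt on demand; structures are small (~130 residues)
        return {r.id: r for r in self.residues}

    def region_residues(self, region: Region) -> list[Residue]:
        return [r for r in self.residues if assign_region(r.id, self.regions) == region]

    def cdr_residues(self) -> list[Residue]:
        return [
            r for r in self.residues
            if assign_region(r.id, self.regions) in ("CDR1", "CDR2", "CDR3")
        ]

    def heavy_atoms(self) -> tuple[list[tuple[ImgtId, str]], np.ndarray]:
        """All heavy atoms as ((residue id, atom name) keys, Nx3 coordinates)."""
        keys: list[tuple[ImgtId, str]] = []
        coords: list[np.ndarray] = []
        for res in self.residues:
            for name, xyz in res.atoms.items():
                keys.append((res.id, name))
                coords.append(xyz)
        return keys, np.asarray(coords, dtype=float).reshape(len(keys), 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NanobodyStructure":
        """Rigid-body copy: x -> R x + t."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        residues = [
            Residue(r.id, r.aa, {n: rot @ c + t for n, c in r.atoms.items()})
            for r in self.residues
        ]
        return NanobodyStructure(residues, source_id=self.source_id, regions=self.regions)


def assign_region(id: ImgtId | int, defs: RegionDefinition = IMGT_REGIONS) -> Region:
    """Map an IMGT position to its framework/CDR region.

    Boundaries are inclusive and insertion codes inherit the region of their
    parent position.  Positions below FR1 or beyond 128 clamp to FR1/FR4.
    """
    pos = id.position if isinstance(id, ImgtId) else id
    if pos < defs.cdr1[0]:
        return "FR1"
    if pos <= defs.cdr1[1]:
        return "CDR1"
    if pos < defs.cdr2[0]:
        return "FR2"
    if pos <= defs.cdr2[1]:
        return "CDR2"
    if pos < defs.cdr3[0]:
        return "FR3"
    if pos <= defs.cdr3[1]:
        return "CDR3"
    return "FR4"


def extract_sequence(s: NanobodyStructure) -> list[tuple[ImgtId, str]]:
    """Numbered sequence in residue order; one (id, aa) pair per residue."""
    return [(r.id, r.aa) for r in s.residues]


def element_of(atom_name: str) -> str:
    """Guess the element from a PDB atom name (hydrogens are not expected)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[0] in "CNOSP":
        return stripped[0]
    return "C"


def parse_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    assume_imgt: bool = True,
) -> NanobodyStructure:
    """Read a single-chain, IMGT-numbered VHH domain from PDB or mmCIF.

    Waters, other heteroatoms and hydrogens are dropped.  For alternate
    locations only the highest-occupancy conformer is kept (ties: first
    encountered).  Residue numbers are interpreted as IMGT positions; when
    ``assume_imgt`` is set, absence of the conserved cysteines (23, 104)
    raises a warning since it suggests the file was not renumbered.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise EmptyStructureError(f"{path}: file is empty")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_ligands_and_waters()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains = [ch for ch in model if any(_is_amino(res) for res in ch)]
    if len(chains) == 0:
        raise EmptyStructureError(f"{path}: no polymer residues")
    if len(chains) > 1:
        names = ", ".join(ch.name for ch in chains)
        raise AmbiguityError(f"{path}: expected one chain, found {len(chains)}: {names}")

    residues: list[Residue] = []
    for res in chains[0]:
        if not _is_amino(res):
            continue
        imgt_id = ImgtId(res.seqid.num, res.seqid.icode.strip())
        aa = _AA3TO1.get(res.name.upper(), "X")
        atoms = _best_altloc_atoms(res)
        if atoms:
            residues.append(Residue(imgt_id, aa, atoms))
    if not residues:
        raise EmptyStructureError(f"{path}: no residues with heavy atoms")
    residues.sort(key=lambda r: r.id)
    _drop_duplicates(residues, path)
    structure = NanobodyStructure(residues, source_id=path.stem)
    if assume_imgt:
        _validate_imgt(structure, path)
    return structure


def _is_amino(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info and info.is_amino_acid())


def _best_altloc_atoms(res: gemmi.Residue) -> dict[str, np.ndarray]:
    best: dict[str, tuple[float, np.ndarray]] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        occ = atom.occ if atom.occ is not None else 1.0
        prev = best.get(atom.name)
        if prev is None or occ > prev[0]:  # tie keeps first encountered
            if prev is None or occ > prev[0]:
                best[atom.name] = (occ, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    return {name: xyz for name, (_, xyz) in best.items()}


def _drop_duplicates(residues: list[Residue], path: Path) -> None:
    seen: set[ImgtId] = set()
    out = []
    for r in residues:
        if r.id in seen:
            warnings.warn(f"{path}: duplicate residue {r.id}, keeping first")
            continue
        seen.add(r.id)
        out.append(r)
    residues[:] = out


def _validate_imgt(s: NanobodyStructure, path: Path) -> None:
    for pos in CONSERVED_CYSTEINES:
        res = s.get(pos)
        if res is None or res.aa != "C":
            warnings.warn(
                f"{path}: conserved cysteine at IMGT {pos} is "
                f"{'absent' if res is None else res.aa}; is this file IMGT-numbered?"
            )


def write_pdb(
    s: NanobodyStructure,
    path: str | Path,
    bfactors: Mapping[tuple[ImgtId, str], float] | None = None,
    chain_name: str = "A",
) -> None:
    """Write the domain as a PDB file.

    ``bfactors`` maps (residue id, atom name) to a scalar stored in the
    B-factor column -- used to export per-atom surface-patch contributions
    for visualisation.  Unlisted atoms get B = 0.
    """
    st = gemmi.Structure()
    st.name = s.source_id or "nanobody"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_name)
    for res in s.residues:
        g = gemmi.Residue()
        g.name = _AA1TO3[res.aa]
        g.seqid = gemmi.SeqId(res.id.position, res.id.insertion or " ")
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element_of(name))
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = float(bfactors.get((res.id, name), 0.0)) if bfactors else 0.0
            g.add_atom(atom)
        chain.add_residue(g)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
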