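"""Solvent accessibility, CDR-vicinity surface patches, tetrad motifs and
sequence liabilities.

Patch scores follow the TAP-style construction: over the *CDR vicinity*
(the CDR loops, their anchors, and any surface residue close in space to a
CDR atom), solvent-exposed heavy-atom pairs within a patch radius are
accumulated with a 1/d distance weight.  Hydrophobic pairs are weighted by
the product of the two residues' hydrophobicity values (Kyte-Doolittle
rescaled to [1, 2]); charge patches use formal side-chain charges (+1 for
Arg/Lys, -1 for Asp/Glu, His configurable).  The exact constants inside the
original TAP implementation are not public; every constant here is a config
key and is echoed in profiling reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from Bio.PDB.DSSP import residue_max_acc
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, GeometryError
from .structure_io import (
    BACKBONE_ATOMS,
    ImgtId,
    NanobodyStructure,
    _AA1TO3,
    assign_region,
    element_of,
)

#: Van der Waals radii (A) by element, hydrogens excluded upstream.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: Kyte-Doolittle hydropathy, later rescaled to [1, 2] for patch scoring.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: Theoretical maximum residue accessibilities (Tien et al. set, A^2),
#: used to turn absolute SASA into relative exposure.
MAX_ACC = residue_max_acc["Wilke"]

POSITIVE_AA = frozenset("RK")
NEGATIVE_AA = frozenset("DE")

#: VHH hallmark tetrad (hydrophilic, exposed FR2) vs the VH motif that is
#: normally buried by the light chain.
VHH_HALLMARK = "FERG"
VH_MOTIF = "VGLW"


def hydrophobicity(aa: str) -> float:
    """Kyte-Doolittle value mapped affinely onto [1, 2]."""
    kd = KYTE_DOOLITTLE.get(aa, 0.0)
    return 1.0 + (kd + 4.5) / 9.0


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    atom_sasa: dict[tuple[ImgtId, str], float]
    residue_sasa: dict[ImgtId, float]
    side_chain_sasa: dict[ImgtId, float]
    relative_sasa: dict[ImgtId, float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.atom_sasa.values()))

    def exposed(self, id: ImgtId, threshold: float) -> bool:
        return self.relative_sasa.get(id, 0.0) >= threshold


@dataclass(frozen=True)
class SurfacePatchScores:
    """TAP-style patch scores over the CDR vicinity (unitless, >= 0)."""

    psh: float
    ppc: float
    pnc: float
    vicinity: frozenset[ImgtId]


@dataclass(frozen=True)
class TetradMotif:
    """Amino acids at the FR2 hallmark positions 42, 49, 50, 52."""

    residues: tuple[str, str, str, str]

    @property
    def motif(self) -> str:
        return "".join(self.residues)

    @property
    def hallmark_class(self) -> Literal["VHH-hallmark", "VH-like", "other"]:
        if self.motif == VHH_HALLMARK:
            return "VHH-hallmark"
        if self.motif == VH_MOTIF:
            return "VH-like"
        return "other"


@dataclass(frozen=True)
class LiabilityHit:
    """A sequence liability motif and whether it sits on the surface."""

    motif_name: str
    motif: str
    positions: tuple[ImgtId, ...]
    surface_exposed: bool


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(s: NanobodyStructure, probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA with a fixed golden-spiral quadrature.

    Deterministic (no RNG): the same structure always yields bit-identical
    areas.  Relative per-residue exposure is the residue's total SASA over
    the theoretical maximum for its amino-acid type.
    """
    keys, coords = s.heavy_atoms()
    if len(keys) == 0:
        raise EmptyStructureError("structure has no heavy atoms")
    radii = np.array([VDW_RADII.get(element_of(name), 1.70) for _, name in keys])
    ext = radii + probe
    points = _sphere_points(n_points)
    tree = cKDTree(coords)
    atom_sasa: dict[tuple[ImgtId, str], float] = {}
    for i, key in enumerate(keys):
        sphere = coords[i] + ext[i] * points
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max())
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        if neighbors:
            d2 = np.min(
                np.sum((sphere[:, None, :] - coords[neighbors][None, :, :]) ** 2, axis=2)
                - ext[neighbors][None, :] ** 2,
                axis=1,
            )
            accessible = int(np.count_nonzero(d2 > 0.0))
        else:
            accessible = n_points
        atom_sasa[key] = 4.0 * np.pi * ext[i] ** 2 * accessible / n_points

    residue_sasa: dict[ImgtId, float] = {}
    side_chain: dict[ImgtId, float] = {}
    for (rid, name), area in atom_sasa.items():
        residue_sasa[rid] = residue_sasa.get(rid, 0.0) + area
        if name not in BACKBONE_ATOMS:
            side_chain[rid] = side_chain.get(rid, 0.0) + area
    relative = {}
    for res in s.residues:
        max_area = MAX_ACC.get(_AA1TO3.get(res.aa, "UNK"), float(np.mean(list(MAX_ACC.values()))))
        relative[res.id] = residue_sasa.get(res.id, 0.0) / max_area
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa,
                      side_chain_sasa=side_chain, relative_sasa=relative,
                      probe=probe, n_points=n_points)


def cdr_vicinity(
    s: NanobodyStructure,
    sasa: SasaResult,
    cutoff: float = 4.0,
    exposure_threshold: float = 0.075,
) -> frozenset[ImgtId]:
    """Residues whose surface makes up the antigen-binding face.

    Surface-exposed CDR residues, the CDR3 anchors (always included), and
    any other surface residue with a heavy atom within ``cutoff`` of a CDR
    heavy atom.
    """
    cdr_ids = {r.id for r in s.cdr_residues()}
    members: set[ImgtId] = {i for i in cdr_ids if sasa.exposed(i, exposure_threshold)}
    for pos in s.regions.cdr3_anchors:
        res = s.get(pos)
        if res is not None:
            members.add(res.id)
    if cdr_ids:
        keys, coords = s.heavy_atoms()
        cdr_mask = np.array([k[0] in cdr_ids for k in keys])
        if cdr_mask.any():
            tree = cKDTree(coords[cdr_mask])
            near = tree.query_ball_point(coords, cutoff)
            for (rid, _), hits in zip(keys, near):
                if rid not in cdr_ids and hits and sasa.exposed(rid, exposure_threshold):
                    members.add(rid)
    return frozenset(members)


def patch_scores(
    s: NanobodyStructure,
    sasa: SasaResult,
    vicinity: Iterable[ImgtId],
    radius: float = 7.5,
) -> SurfacePatchScores:
    """1/d-weighted pair sums over exposed heavy atoms of the vicinity.

    PSH multiplies each pair by the product of the two residues'
    hydrophobicity values; PPC/PNC by the product of formal charges of
    positive (R, K) / negative (D, E) residues.  Pairs within one residue
    are excluded -- their distances reflect covalent geometry, not surface
    packing.
    """
    vicinity = frozenset(vicinity)
    aa_of = {r.id: r.aa for r in s.residues}
    coord_map = {(r.id, n): c for r in s.residues for n, c in r.atoms.items()}
    keys = [k for k, area in sasa.atom_sasa.items() if k[0] in vicinity and area > 0.0]
    coords = np.array([coord_map[k] for k in keys]) if keys else np.empty((0, 3))

    psh = ppc = pnc = 0.0
    if len(keys) >= 2:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(radius):
            ri, rj = keys[i][0], keys[j][0]
            if ri == rj:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d == 0.0:
                raise GeometryError(f"coincident atoms {keys[i]} and {keys[j]}")
            ai, aj = aa_of[ri], aa_of[rj]
            psh += hydrophobicity(ai) * hydrophobicity(aj) / d
            if ai in POSITIVE_AA and aj in POSITIVE_AA:
                ppc += 1.0 / d
            if ai in NEGATIVE_AA and aj in NEGATIVE_AA:
                pnc += 1.0 / d
    return SurfacePatchScores(psh=psh, ppc=ppc, pnc=pnc, vicinity=vicinity)


def patch_contributions(
    s: NanobodyStructure,
    sasa: SasaResult,
    vicinity: Iterable[ImgtId],
    radius: float = 7.5,
) -> dict[tuple[ImgtId, str], float]:
    """Per-atom share of the PSH sum (half of each pair term to each atom).

    Intended for the B-factor column of an annotated PDB so patches can be
    inspected in a molecular viewer.
    """
    vicinity = frozenset(vicinity)
    aa_of = {r.id: r.aa for r in s.residues}
    coord_map = {(r.id, n): c for r in s.residues for n, c in r.atoms.items()}
    keys = [k for k, area in sasa.atom_sasa.items() if k[0] in vicinity and area > 0.0]
    out: dict[tuple[ImgtId, str], float] = {}
    if len(keys) >= 2:
        coords = np.array([coord_map[k] for k in keys])
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(radius):
            if keys[i][0] == keys[j][0]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            term = hydrophobicity(aa_of[keys[i][0]]) * hydrophobicity(aa_of[keys[j][0]]) / d
            out[keys[i]] = out.get(keys[i], 0.0) + 0.5 * term
            out[keys[j]] = out.get(keys[j], 0.0) + 0.5 * term
    return out


def tetrad_motif(s: NanobodyStructure) -> TetradMotif:
    """Hallmark residues at IMGT 42, 49, 50, 52; '-' where absent."""
    aas = []
    for pos in s.regions.tetrad_positions:
        res = s.get(pos)
        aas.append(res.aa if res is not None else "-")
    return TetradMotif(residues=tuple(aas))


#: (name, motif pattern) scanned over sequence-adjacent residues.
_PAIR_MOTIFS = (
    ("deamidation", "NG"),
    ("deamidation", "NS"),
    ("isomerization", "DG"),
    ("isomerization", "DP"),
)


def detect_liabilities(
    s: NanobodyStructure,
    sasa: SasaResult,
    exposure_threshold: float = 0.075,
) -> list[LiabilityHit]:
    """Scan the IMGT-ordered sequence for chemical liability motifs.

    Deamidation (NG/NS), isomerization (DG/DP), N-glycosylation sequons
    (N-x-S/T with x != P), cysteines outside the conserved 23/104 pair, and
    oxidation-prone Met/Trp.  A hit is surface-exposed when every one of
    its residues passes the relative-SASA threshold.  The motif list is a
    deliberately minimal, heuristic set.
    """
    seq = [(r.id, r.aa) for r in s.residues]
    hits: list[LiabilityHit] = []

    def exposed_all(ids: tuple[ImgtId, ...]) -> bool:
        return all(sasa.exposed(i, exposure_threshold) for i in ids)

    for (i1, a1), (i2, a2) in zip(seq, seq[1:]):
        for name, motif in _PAIR_MOTIFS:
            if a1 + a2 == motif:
                ids = (i1, i2)
                hits.append(LiabilityHit(name, motif, ids, exposed_all(ids)))
    for (i1, a1), (i2, a2), (i3, a3) in zip(seq, seq[1:], seq[2:]):
        if a1 == "N" and a2 != "P" and a3 in "ST":
            ids = (i1, i2, i3)
            hits.append(LiabilityHit("glycosylation", a1 + a2 + a3, ids, exposed_all(ids)))
    conserved = {23, 104}
    for rid, aa in seq:
        if aa == "C" and rid.position not in conserved:
            hits.append(LiabilityHit("unpaired-cysteine", "C", (rid,), exposed_all((rid,))))
        elif aa in "MW":
            hits.append(LiabilityHit("oxidation", aa, (rid,), exposed_all((rid,))))
    return hits
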