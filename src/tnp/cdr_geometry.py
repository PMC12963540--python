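"""CDR loop geometry: lengths, CDR3 reach/compactness, kink classification,
and bound/unbound pairwise comparison.

The CDR3 conformation of a VHH is summarised by *compactness*: the loop
length in residues divided by its *reach*, the distance in Angstrom from the
loop's anchor point to its furthest CA atom.  A loop of low compactness
extends away from the variable domain (antibody CDR-H3-like); a loop of
high compactness folds down over the exposed FR2 surface.  The discrete
kinked/extended classification of the loop base is computed from two
pseudo-angles over backbone CA atoms near the C-terminal anchor:
a signed pseudo-dihedral (alpha116) and a planar pseudo-bond angle (tau116).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AnchorError,
    AngleError,
    EmptyLoopError,
    PairingError,
    SuperpositionError,
)
from .structure_io import ImgtId, NanobodyStructure, Region, assign_region

#: Compactness cut-point separating the two CDR3 conformational subtypes.
COMPACTNESS_THRESHOLD = 1.25

#: Kinked window: 0 < alpha116 < 120 and 85 < tau116 < 130 (degrees, open).
KINKED_ALPHA = (0.0, 120.0)
KINKED_TAU = (85.0, 130.0)
#: Extended window: alpha116 < -100 and 100 < tau116 < 145 (degrees, open).
EXTENDED_ALPHA_MAX = -100.0
EXTENDED_TAU = (100.0, 145.0)


@dataclass(frozen=True)
class Cdr3Geometry:
    """CDR3 length, reach and their ratio (compactness, residues per A)."""

    length: int
    reach: float
    compactness: float
    anchor_point: np.ndarray

    @property
    def subtype(self) -> Literal["lower", "higher"]:
        return compactness_subtype(self.compactness)


@dataclass(frozen=True)
class KinkAngles:
    """Pseudo-dihedral and pseudo-bond angle at the CDR3 base, with label.

    alpha116 is the signed dihedral over CA(115)-CA(116)-CA(117)-CA(118)
    in (-180, 180]; tau116 the planar angle over CA(116)-CA(117)-CA(118)
    in [0, 180].
    """

    alpha116: float
    tau116: float

    @property
    def label(self) -> Literal["kinked", "extended", "other"]:
        return classify_kink(self.alpha116, self.tau116)


@dataclass(frozen=True)
class PairComparison:
    """Bound-vs-unbound CDR3 comparison after framework superposition."""

    delta_compactness: float
    cdr3_rmsd: float
    n_framework: int
    n_cdr3: int


def classify_kink(alpha: float, tau: float) -> Literal["kinked", "extended", "other"]:
    """Label a (alpha116, tau116) pair; windows are open intervals.

    The two windows are mutually exclusive by construction: kinked requires
    alpha > 0 while extended requires alpha < -100.
    """
    if KINKED_ALPHA[0] < alpha < KINKED_ALPHA[1] and KINKED_TAU[0] < tau < KINKED_TAU[1]:
        return "kinked"
    if alpha < EXTENDED_ALPHA_MAX and EXTENDED_TAU[0] < tau < EXTENDED_TAU[1]:
        return "extended"
    return "other"


def compactness_subtype(
    compactness: float, threshold: float = COMPACTNESS_THRESHOLD
) -> Literal["lower", "higher"]:
    """Partition at the cut-point; a value exactly at threshold is 'higher'."""
    return "higher" if compactness >= threshold else "lower"


def cdr_length(s: NanobodyStructure, region: Region) -> int:
    """Number of residues (insertion codes included) in a CDR span."""
    if region not in ("CDR1", "CDR2", "CDR3"):
        raise ValueError(f"not a CDR region: {region}")
    return sum(1 for r in s.residues if assign_region(r.id, s.regions) == region)


def total_cdr_length(s: NanobodyStructure) -> int:
    return sum(cdr_length(s, r) for r in ("CDR1", "CDR2", "CDR3"))


def _anchor_point(s: NanobodyStructure) -> np.ndarray:
    """Midpoint of the CA atoms of the two CDR3 anchors (IMGT 104 and 118)."""
    cas = []
    for pos in s.regions.cdr3_anchors:
        res = s.get(pos)
        if res is None or res.ca is None:
            raise AnchorError(f"CDR3 anchor {pos}: residue or CA atom missing")
        cas.append(res.ca)
    return 0.5 * (cas[0] + cas[1])


def cdr3_reach(s: NanobodyStructure) -> float:
    """Max distance (A) from the anchor point to any CDR3 CA atom."""
    anchor = _anchor_point(s)
    loop_cas = [r.ca for r in s.region_residues("CDR3") if r.ca is not None]
    if not loop_cas:
        raise EmptyLoopError("CDR3 span contains no residues with CA atoms")
    return float(np.max(np.linalg.norm(np.asarray(loop_cas) - anchor, axis=1)))


def cdr3_compactness(s: NanobodyStructure) -> Cdr3Geometry:
    """Length / reach; > 1.25 means the loop folds against the domain."""
    anchor = _anchor_point(s)
    reach = cdr3_reach(s)
    length = cdr_length(s, "CDR3")
    return Cdr3Geometry(length=length, reach=reach,
                        compactness=length / reach, anchor_point=anchor)


def pseudo_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, atan2 formulation, (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle == -180.0 else float(angle)


def pseudo_angle(p0, p1, p2) -> float:
    """Planar angle at p1 in degrees, [0, 180]."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def kink_angles(s: NanobodyStructure, dihedral_quadruple: tuple[int, int, int, int] = (115, 116, 117, 118)) -> KinkAngles:
    """Compute (alpha116, tau116) from CA atoms near the CDR3 C-terminal base.

    The default convention takes the signed dihedral over CA 115-116-117-118
    and the planar angle over CA 116-117-118; an alternative quadruple (e.g.
    116-117-118-119) can be supplied since published descriptions name only
    the positions 116-118.
    """
    cas = {}
    needed = sorted(set(dihedral_quadruple))
    for pos in needed:
        res = s.get(pos)
        if res is None or res.ca is None:
            raise AngleError(f"CA atom missing at IMGT {pos} (needed for kink angles)")
        cas[pos] = res.ca
    q = dihedral_quadruple
    alpha = pseudo_dihedral(cas[q[0]], cas[q[1]], cas[q[2]], cas[q[3]])
    tau = pseudo_angle(cas[q[1]], cas[q[2]], cas[q[3]])
    return KinkAngles(alpha116=alpha, tau116=tau)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R@x+t fitting target."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    r = rot.as_matrix()
    return r, ct - r @ cm


def compare_pair(bound: NanobodyStructure, unbound: NanobodyStructure) -> PairComparison:
    """Superpose on shared framework CAs, then compare CDR3 conformations.

    Returns the signed compactness change (bound - unbound) and the CDR3 CA
    RMSD after a Kabsch superposition of the unbound framework onto the
    bound framework.
    """
    def ca_map(s: NanobodyStructure) -> dict[ImgtId, np.ndarray]:
        return {r.id: r.ca for r in s.residues if r.ca is not None}

    b_ca, u_ca = ca_map(bound), ca_map(unbound)
    shared = sorted(set(b_ca) & set(u_ca))
    fw_ids = [i for i in shared
              if assign_region(i, bound.regions) not in ("CDR1", "CDR2", "CDR3")]
    if len(fw_ids) < 3:
        raise SuperpositionError(
            f"only {len(fw_ids)} shared framework CA atoms; need >= 3")
    cdr3_ids = [i for i in shared if assign_region(i, bound.regions) == "CDR3"]
    if not cdr3_ids:
        raise PairingError("bound and unbound structures share no CDR3 residues")

    r, t = kabsch(np.array([u_ca[i] for i in fw_ids]),
                  np.array([b_ca[i] for i in fw_ids]))
    u_fit = np.array([r @ u_ca[i] + t for i in cdr3_ids])
    b_pts = np.array([b_ca[i] for i in cdr3_ids])
    rmsd = float(np.sqrt(np.mean(np.sum((u_fit - b_pts) ** 2, axis=1))))
    delta = cdr3_compactness(bound).compactness - cdr3_compactness(unbound).compactness
    return PairComparison(delta_compactness=delta, cdr3_rmsd=rmsd,
                          n_framework=len(fw_ids), n_cdr3=len(cdr3_ids))
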