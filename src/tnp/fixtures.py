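"""Synthetic nanobody-like structures with controlled geometry and sequence.

These generators exist so that every metric can be exercised, and checked
against closed-form expectations, without downloading structures or running
a structure predictor.  The geometry is deliberately idealized, not
physically realistic: framework CA atoms sit on a serpentine grid, the
CDR3 CA trace follows a chord path from anchor 104 up to an apex and back
down to anchor 118, and side chains are reduced to a CB plus one
pseudo-centroid atom sized per residue type (enough surface geometry for
SASA and patch scoring).

The apex CA is placed analytically at the requested reach from the anchor
midpoint, and every other loop CA is strictly closer, so the realized reach
equals the requested one exactly and compactness is an analytic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleSpecError
from .structure_io import ImgtId, NanobodyStructure, Residue, RegionDefinition

#: CA-CA virtual bond length (A) used for the feasibility bound.
CA_STEP = 3.8

#: Anchor CA placement: IMGT 104 and 118 flank the loop base.
_ANCHOR_104 = np.array([0.0, 0.0, 0.0])
_ANCHOR_118 = np.array([7.6, 0.0, 0.0])

#: Rough side-chain bulk (heavy-atom count) per residue type, used to size
#: the pseudo-centroid atom.
_SIDE_CHAIN_SIZE = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 3, "V": 3, "P": 3,
    "I": 4, "L": 4, "N": 4, "D": 4, "M": 4, "E": 5, "Q": 5,
    "K": 5, "H": 6, "R": 7, "F": 7, "Y": 8, "W": 10, "X": 3,
}

_CDR_ALPHABET = list("SGYNTDARKFVLEW")


@dataclass
class FixtureSpec:
    """Controls for one synthetic nanobody.

    ``target_reach`` is the exact CDR3 reach (A) the built structure will
    realize; ``tetrad`` the FR2 hallmark motif at 42/49/50/52; CDR
    sequences default to a seed-determined draw.  ``insertions`` adds
    extra residues at the given IMGT ids (e.g. ``111A``).
    """

    cdr3_length: int = 13
    target_reach: float = 10.0
    tetrad: str = "FERG"
    cdr1_seq: str | None = None
    cdr2_seq: str | None = None
    cdr3_seq: str | None = None
    framework_aa: str = "S"
    sequence_overrides: dict[int, str] = field(default_factory=dict)
    insertions: list[ImgtId] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cdr3_length < 1:
            raise InfeasibleSpecError(f"cdr3_length must be >= 1, got {self.cdr3_length}")
        if len(self.tetrad) != 4:
            raise InfeasibleSpecError(f"tetrad must have 4 letters, got {self.tetrad!r}")


def _cdr3_ids(length: int, extra_insertions: int = 0) -> list[ImgtId]:
    """IMGT ids for a CDR3 of the given length within the 105-117 span.

    Short loops vacate the middle of the span (filled from both ends);
    loops longer than 13 gain insertion codes at position 111 (plain
    alphabetical order -- the bidirectional IMGT convention is simplified).
    """
    span = list(range(105, 118))
    if length <= 13:
        head = math.ceil(length / 2)
        tail = length - head
        ids = [ImgtId(p) for p in span[:head]] + [ImgtId(p) for p in span[13 - tail:]]
    else:
        ids = [ImgtId(p) for p in span[:7]]
        ids += [ImgtId(111, chr(ord("A") + i)) for i in range(length - 13)]
        ids += [ImgtId(p) for p in span[7:]]
    return ids


def _cdr3_trace(n: int, reach: float) -> np.ndarray:
    """CA positions for an n-residue loop whose reach is exactly ``reach``.

    The trace follows the circle through both anchors whose top point lies
    at ``reach`` from the anchor midpoint; the middle CA is pinned at that
    apex (so the realized reach is exact) and every other CA sits strictly
    closer.  Intermediate points get a small alternating lateral offset to
    avoid exactly collinear pseudo-angle atoms, guarded so they stay
    strictly inside the reach sphere.
    """
    mid = 0.5 * (_ANCHOR_104 + _ANCHOR_118)
    half_sep = 0.5 * float(np.linalg.norm(_ANCHOR_118 - _ANCHOR_104))
    # circle in the xz-plane: center above the midpoint, apex at its top
    z0 = (reach**2 - half_sep**2) / (2.0 * reach)
    radius = reach - z0
    center = mid + np.array([0.0, 0.0, z0])
    phi_anchor = math.atan2(half_sep / radius, -z0 / radius)  # angle of anchors from apex
    k_apex = math.ceil(n / 2)  # 1-based index pinned at the apex

    def on_circle(phi: float) -> np.ndarray:
        return center + radius * np.array([math.sin(phi), 0.0, math.cos(phi)])

    pts = np.empty((n, 3))
    for k in range(1, n + 1):
        if k == k_apex:
            phi = 0.0
        elif k < k_apex:
            phi = -phi_anchor * (1.0 - k / k_apex)
        else:
            phi = phi_anchor * (k - k_apex) / (n + 1 - k_apex)
        pts[k - 1] = on_circle(phi)
        if k != k_apex:
            jitter = np.array([0.0, 0.35 * (-1.0) ** k, 0.0])
            if np.linalg.norm(pts[k - 1] + jitter - mid) < reach - 0.05:
                pts[k - 1] += jitter
    return pts


def _side_chain(aa: str, ca: np.ndarray, direction: np.ndarray) -> dict[str, np.ndarray]:
    if aa == "G":
        return {}
    u = direction / np.linalg.norm(direction)
    ext = 0.8 + 0.35 * _SIDE_CHAIN_SIZE.get(aa, 3)
    return {"CB": ca + 1.5 * u, "CG": ca + (1.5 + ext) * u}


def _backbone(ca: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "N": ca + np.array([-1.2, 0.0, 0.45]),
        "C": ca + np.array([1.2, 0.0, 0.45]),
        "O": ca + np.array([1.9, 0.0, 1.25]),
    }


def make_toy_nanobody(spec: FixtureSpec, regions: RegionDefinition | None = None) -> NanobodyStructure:
    """Build one IMGT-numbered synthetic VHH domain from a spec.

    Raises :class:`InfeasibleSpecError` when no chain of ``cdr3_length``
    virtual bonds can place a CA at ``target_reach``.
    """
    regions = regions or RegionDefinition()
    half_sep = float(np.linalg.norm(_ANCHOR_118 - _ANCHOR_104)) / 2.0
    if spec.target_reach >= CA_STEP * spec.cdr3_length:
        raise InfeasibleSpecError(
            f"reach {spec.target_reach} A not reachable by a {spec.cdr3_length}-residue "
            f"loop of {CA_STEP} A virtual bonds")
    if spec.target_reach <= half_sep + 0.2:
        raise InfeasibleSpecError(
            f"reach {spec.target_reach} A must exceed the anchor half-separation "
            f"({half_sep:.1f} A)")

    rng = np.random.default_rng(spec.seed)
    cdr1 = spec.cdr1_seq if spec.cdr1_seq is not None else "".join(rng.choice(_CDR_ALPHABET, size=12))
    cdr2 = spec.cdr2_seq if spec.cdr2_seq is not None else "".join(rng.choice(_CDR_ALPHABET, size=10))
    cdr3 = spec.cdr3_seq if spec.cdr3_seq is not None else "".join(rng.choice(_CDR_ALPHABET, size=spec.cdr3_length))
    if len(cdr3) != spec.cdr3_length:
        raise InfeasibleSpecError(
            f"cdr3_seq has {len(cdr3)} residues but cdr3_length is {spec.cdr3_length}")

    aa_at: dict[ImgtId, str] = {}
    for offset, pos in enumerate(range(regions.cdr1[0], regions.cdr1[0] + len(cdr1))):
        aa_at[ImgtId(pos)] = cdr1[offset]
    for offset, pos in enumerate(range(regions.cdr2[0], regions.cdr2[0] + len(cdr2))):
        aa_at[ImgtId(pos)] = cdr2[offset]
    cdr3_ids = _cdr3_ids(spec.cdr3_length)
    for rid, aa in zip(cdr3_ids, cdr3):
        aa_at[rid] = aa

    for pos in range(1, 129):
        rid = ImgtId(pos)
        if rid in aa_at or regions.cdr3[0] <= pos <= regions.cdr3[1]:
            continue
        if regions.cdr1[0] <= pos <= regions.cdr1[1] or regions.cdr2[0] <= pos <= regions.cdr2[1]:
            continue  # trimmed CDR positions stay vacant
        aa_at[rid] = spec.framework_aa
    for pos, aa4 in zip(regions.tetrad_positions, spec.tetrad):
        aa_at[ImgtId(pos)] = aa4
    aa_at[ImgtId(23)] = "C"
    aa_at[ImgtId(104)] = "C"
    aa_at[ImgtId(118)] = "W"
    for pos, aa in spec.sequence_overrides.items():
        aa_at[ImgtId(pos)] = aa
    for rid in spec.insertions:
        aa_at.setdefault(rid, spec.framework_aa)

    ordered = sorted(aa_at)
    cdr3_set = set(cdr3_ids) | {
        i for i in spec.insertions if regions.cdr3[0] <= i.position <= regions.cdr3[1]}
    loop_ids = [i for i in ordered if i in cdr3_set]
    trace = _cdr3_trace(len(loop_ids), spec.target_reach)
    loop_ca = dict(zip(loop_ids, trace))

    residues: list[Residue] = []
    grid_index = 0
    mid = 0.5 * (_ANCHOR_104 + _ANCHOR_118)
    for rid in ordered:
        aa = aa_at[rid]
        if rid.position == 104 and not rid.insertion:
            ca = _ANCHOR_104.copy()
            sc_dir = np.array([-0.5, 0.3, -1.0])
        elif rid.position == 118 and not rid.insertion:
            ca = _ANCHOR_118.copy()
            sc_dir = np.array([0.5, 0.3, -1.0])
        elif rid in loop_ca:
            ca = loop_ca[rid]
            radial = ca - mid
            sc_dir = radial if np.linalg.norm(radial) > 1e-6 else np.array([0.0, 1.0, 0.0])
        else:
            row, col = divmod(grid_index, 12)
            x = 3.8 * col if row % 2 == 0 else 3.8 * (11 - col)  # serpentine
            ca = np.array([x - 15.2, 0.0, -5.0 - 5.5 * row])
            sc_dir = np.array([0.0, 1.0 if grid_index % 2 == 0 else -1.0, 0.0])
            grid_index += 1
        atoms = {"CA": ca, **_backbone(ca), **_side_chain(aa, ca, sc_dir)}
        residues.append(Residue(rid, aa, atoms))
    return NanobodyStructure(residues, source_id=f"toy_seed{spec.seed}")


def kink_quadruple(alpha: float, tau: float, bond: float = CA_STEP,
                   bond_angle: float = 114.0) -> dict[int, np.ndarray]:
    """CA coordinates at IMGT 115-118 with exact pseudo-angles.

    Closed-form placement: CA118 at the origin, CA117 on +x, CA116 in the
    xy-plane at planar angle ``tau``, and CA115 placed by internal-to-
    Cartesian construction so that the signed dihedral over 115-116-117-118
    equals ``alpha`` (degrees).
    """
    a = np.radians(alpha)
    t = np.radians(tau)
    th = np.radians(bond_angle)
    ca118 = np.zeros(3)
    ca117 = np.array([bond, 0.0, 0.0])
    ca116 = ca117 + bond * np.array([-np.cos(t), np.sin(t), 0.0])
    # NeRF: place D=115 from A=118, B=117, C=116 with torsion(A,B,C,D)=alpha
    bc = ca116 - ca117
    bc /= np.linalg.norm(bc)
    ab = ca117 - ca118
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(th),
                   bond * np.sin(th) * np.cos(a),
                   -bond * np.sin(th) * np.sin(a)])
    ca115 = ca116 + d2[0] * bc + d2[1] * m + d2[2] * n
    return {115: ca115, 116: ca116, 117: ca117, 118: ca118}


def make_kink_probe(alpha: float, tau: float) -> NanobodyStructure:
    """Minimal structure carrying only the four CA atoms the kink
    classification reads (IMGT 115-118)."""
    cas = kink_quadruple(alpha, tau)
    residues = [Residue(ImgtId(pos), "G", {"CA": xyz}) for pos, xyz in sorted(cas.items())]
    return NanobodyStructure(residues, source_id=f"kink_{alpha:+.0f}_{tau:.0f}")


def make_reference_set(
    n: int,
    seed: int = 0,
    cdr3_length_range: tuple[int, int] = (9, 17),
    compactness_range: tuple[float, float] = (0.85, 2.0),
) -> list[NanobodyStructure]:
    """A calibration panel of ``n`` synthetic structures spanning the
    metric ranges (mirrors the role of a clinical-stage reference set).

    Loop length and compactness are drawn per molecule and the reach set to
    their ratio; CDR sequences are drawn from a mixed alphabet so patch
    scores vary.  Fully deterministic per seed.
    """
    if n < 2:
        raise InfeasibleSpecError(f"reference set needs n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    structures = []
    for i in range(n):
        length = int(rng.integers(cdr3_length_range[0], cdr3_length_range[1] + 1))
        compactness = float(rng.uniform(*compactness_range))
        reach = length / compactness
        reach = float(np.clip(reach, 4.3, CA_STEP * length - 0.2))
        cdr1_len = int(rng.integers(10, 13))
        cdr2_len = int(rng.integers(8, 11))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        spec = FixtureSpec(
            cdr3_length=length,
            target_reach=reach,
            cdr1_seq="".join(sub_rng.choice(_CDR_ALPHABET, size=cdr1_len)),
            cdr2_seq="".join(sub_rng.choice(_CDR_ALPHABET, size=cdr2_len)),
            seed=sub_seed,
        )
        s = make_toy_nanobody(spec)
        s.source_id = f"ref_{i+1:03d}"
        structures.append(s)
    return structures
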