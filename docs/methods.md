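# Methods

This note documents the models and conventions behind each computed
quantity, the tunable parameters and their defaults, what the synthetic
generators do and do not emulate, and the design choices made where the
underlying method descriptions leave room.

## Input contract: IMGT numbering

Residue numbers in input PDB/mmCIF files are taken to *be* IMGT positions
(insertion codes included). The package does not renumber sequences;
inputs are expected from an antibody-numbering pipeline or a structure
predictor that emits IMGT numbering. Parsing validates the contract
heuristically: absence of the conserved cysteines at positions 23 and 104
raises a warning. Regions are fixed spans — CDR1 27–38, CDR2 56–65,
CDR3 105–117, anchors 104/118, tetrad 42/49/50/52 — with inclusive
boundaries, and an inserted residue (e.g. 111A) inherits the region of its
parent position. IMGT's bidirectional insertion ordering inside the
111/112 block is simplified to plain alphabetical order within a position:
ordering affects only sequence display, never a metric (lengths count
residues; geometry uses coordinates).

Parsing drops waters, heteroatoms and hydrogens; for alternate locations
the highest-occupancy conformer is kept (ties: first encountered). Exactly
one polypeptide chain is required.

## CDR3 compactness

`compactness = length / reach`, where length is the CDR3 residue count and
reach is the maximum Euclidean distance (Å) from the anchor point to a
CDR3 Cα atom. Two conventions had to be fixed:

* **Anchor point** — the midpoint of Cα(104) and Cα(118). This is
  symmetric in both anchors and well defined; alternatives (one anchor
  only, or the max over both) change reach by well under the spread
  between conformational subtypes.
* **"Furthest point"** — measured over Cα atoms, consistent with the
  Cα-level kink angles. (An all-heavy-atom reach would mix side-chain
  size into a backbone-shape descriptor.)

Structures missing an anchor Cα raise an error rather than guessing a
substitute anchor. The subtype cut-point is 1.25 (residues/Å); a value
exactly at the cut-point is classified "higher" — a deterministic
tie-break on a measure-zero boundary.

## Kinked / extended classification

The loop base is described by a signed pseudo-dihedral α116 over
Cα(115)–Cα(116)–Cα(117)–Cα(118) (atan2 formulation, degrees, (−180, 180])
and a planar pseudo-bond angle τ116 over Cα(116)–Cα(117)–Cα(118)
([0, 180]). Windows (all bounds open):

* kinked: 0° < α116 < 120° and 85° < τ116 < 130°
* extended: α116 < −100° and 100° < τ116 < 145°
* otherwise: "other"

The windows are mutually exclusive (kinked needs α > 0, extended α < −100).
Published descriptions name only "positions 116, 117 and 118" for the two
angles; a dihedral needs four atoms, so the default quadruple extends one
position N-terminal (115–118). Both raw angles are always reported, and
`kink_angles` accepts an alternative quadruple (e.g. 116–119) so labels
can be re-derived under the other plausible convention.

## Bound/unbound comparison

`compare_pair` superposes the unbound structure onto the bound one by
least-squares (Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`)
over shared framework Cα atoms (≥ 3 required), then reports the Cα RMSD
over shared CDR3 positions and the signed compactness change
(bound − unbound). Compactness itself is superposition-free, so the RMSD
isolates conformational change from the compactness delta.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-section spiral point set
(default 960 points/atom, probe 1.4 Å) — no RNG, so areas are bit-stable
across runs. Van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å. The
quadrature reproduces the closed form for an isolated sphere and a
two-sphere system to well under 1 %, and agrees with an independent
implementation (biotite) to ~0.1 % on full structures.

Relative exposure is computed per residue as total residue SASA over the
theoretical maximum for its amino-acid type (Tien et al. theoretical set,
as tabulated in Biopython). The side-chain-only SASA sums are reported as
well, but exposure gating uses the whole-residue ratio: no authoritative
side-chain-only maxima ship with the dependency stack, and the synthetic
fixtures use reduced side chains for which a side-chain-only fraction
would be ill-scaled. The exposure threshold (default 7.5 %) is a config
key; with reduced-atom fixtures relative values above 1 are possible and
harmless (gating is one-sided).

## Surface patch scores (PSH, PPC, PNC)

Patch scoring is a reconstruction of the TAP-style approach; the original
implementation's exact constants are not public, so every constant here is
explicit, configurable, and echoed into reports:

* **Vicinity** — surface-exposed CDR residues, the CDR3 anchors (always
  included), plus any other surface residue with a heavy atom within
  4.0 Å of a CDR heavy atom.
* **Pair set** — unordered pairs of solvent-exposed heavy atoms (per-atom
  SASA > 0) from *distinct* vicinity residues within 7.5 Å. Intra-residue
  pairs are excluded: their distances are covalent geometry, not surface
  packing.
* **PSH** — Σ H(i)·H(j)/d_ij with H the Kyte–Doolittle value rescaled
  affinely to [1, 2] (so even hydrophilic residues contribute positively,
  weighted up for hydrophobic ones).
* **PPC / PNC** — Σ q_i·q_j/d_ij over atoms of Arg/Lys (+1) for PPC, and
  |q_i·q_j|/d_ij over Asp/Glu (−1) for PNC. Histidine is neutral by
  default (`+0.5` would be a defensible alternative at endosomal pH; the
  charge table is a single point of change).

All three scores are non-negative, zero for an empty vicinity, exactly
invariant under rigid-body motion (given fixed exposure gating), and
monotone non-decreasing when qualifying pairs are added.

## Tetrad motif and liabilities

The tetrad concatenates the residues at IMGT 42, 49, 50, 52 ('-' for a
missing position): `FERG` → VHH-hallmark, `VGLW` → VH-like, anything else
"other". The liability scan is a deliberately minimal heuristic set over
the IMGT-ordered sequence: NG/NS (deamidation), DG/DP (isomerization),
N-x-[S/T] with x ≠ P (N-glycosylation sequon), cysteines outside the
conserved 23/104 pair, and Met/Trp (oxidation). A hit is "surface exposed"
iff every motif residue passes the exposure threshold.

## Flagging

For each metric the candidate value is placed on the reference
distribution by midrank empirical percentile,
`(#below + 0.5·#equal) / N`. Red requires the value to lie *strictly*
outside [min, max] of the reference — a value exactly at the observed
extreme is inside the range and flags amber (it is necessarily within a
tail). Amber is percentile ≤ 5 % or ≥ 95 % (two-sided by default;
per-metric one-sidedness is a policy option, since e.g. unusually low
hydrophobicity is plausibly benign). With N = 36 the 5 % tail covers
roughly the two extreme reference values. No interpolation scheme is
needed: flags depend only on counts, so they are invariant under
permutation of the reference and stable through CSV round trips.

The package ships no clinical reference values. `calibrate` builds the six
distributions from any panel of profileable structures and reads/writes
the CSV schema `molecule_id,total_cdr_length,cdr3_length,cdr3_compactness,
psh,ppc,pnc`; structures that fail profiling are skipped with a warning
and the final count reported.

## Synthetic fixtures

`make_toy_nanobody` emits an IMGT-numbered single-chain domain:

* framework Cα atoms on a serpentine grid (12 per row, 3.8 Å along rows);
* CDR3 Cα atoms on the circle through both anchors whose apex lies exactly
  `target_reach` from the anchor midpoint; the middle Cα is pinned at the
  apex and all others are strictly closer, so the realized reach equals
  the request analytically (a small alternating lateral offset, guarded to
  stay inside the reach sphere, avoids degenerate collinear pseudo-angle
  atoms). Infeasible requests (reach ≥ 3.8 Å × length, or reach below the
  anchor half-separation) raise an error;
* side chains reduced to CB plus a pseudo-centroid carbon whose extension
  scales with the residue type's heavy-atom count — enough surface
  geometry to exercise SASA and patch scoring without a rotamer library;
* conserved C23/C104/W118, the requested tetrad, and seed-determined CDR
  sequences. Generation is fully deterministic per seed.

`make_reference_set` draws loop length (9–17 residues) and compactness
(0.85–2.0, straddling both subtypes and matching the bimodal range seen in
real VHH data) per molecule, sets reach to their ratio, and varies CDR1/2
lengths (10–12 / 8–10) and CDR sequences. It mirrors the *role* of a
36-molecule clinical-stage calibration panel, not its values.

What the fixtures do **not** emulate: real backbone connectivity between
framework and loop, rotamers, Ramachandran validity, realistic packing
density, or clinical metric distributions. Passing tests therefore
demonstrate correctness of the computations and contracts, not that any
threshold derived from synthetic panels is transferable to real molecules
— real calibration data must be supplied for that.

`kink_quadruple` places four Cα atoms by internal-to-Cartesian
construction so the requested (α, τ) are realized exactly, which makes the
classification windows testable at their printed boundaries.

## Problem sizes and numerics

Unit and integration tests run on single domains (~128 residues,
~600 heavy atoms) and 5–36-molecule panels; the acceptance script uses a
36-molecule panel, matching the size of the clinical calibration set the
flagging scheme is designed around. SASA for one domain takes well under a
second at 960 points/atom; quadrature accuracy at that density is ~0.3 %
against closed forms, an order of magnitude tighter than the 1 % the
checks require. Degenerate inputs are errors, not silent results: empty
CDR3, missing anchor/kink Cα atoms, coincident atoms at zero pair
distance, non-finite metric values, references with fewer than two values.
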