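import itertools

import numpy as np
import pytest

from tnp import structure_io as sio
from tnp import surface_metrics as sm
from tnp.errors import EmptyStructureError
from tnp.fixtures import FixtureSpec, make_toy_nanobody

from conftest import random_rotation, single_atom_structure

CARBON_EXT = 1.70 + 1.4  # vdW + probe radius


class TestComputeSasa:
    def test_isolated_sphere_closed_form(self):
        res = sm.compute_sasa(single_atom_structure())
        exact = 4 * np.pi * CARBON_EXT**2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_fully_caged_atom_is_buried(self):
        # central atom surrounded by an icosahedral cage 2 A away
        phi = (1 + 5**0.5) / 2
        dirs = []
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                dirs += [np.array([0, s1, s2 * phi]), np.array([s1, s2 * phi, 0]),
                         np.array([s2 * phi, 0, s1])]
        coords = [np.zeros(3)] + [2.0 * v / np.linalg.norm(v) for v in dirs]
        res = sm.compute_sasa(single_atom_structure(coords))
        assert res.atom_sasa[(sio.ImgtId(1), "CA")] == 0.0

    def test_two_sphere_closed_form(self):
        # equal carbon spheres at distance d: exposed area has a closed form
        d = 3.0
        res = sm.compute_sasa(single_atom_structure([(0, 0, 0), (d, 0, 0)]))
        cap_height = CARBON_EXT - d / 2
        exact_each = 4 * np.pi * CARBON_EXT**2 - 2 * np.pi * CARBON_EXT * cap_height
        for key, area in res.atom_sasa.items():
            assert area == pytest.approx(exact_each, rel=0.01)

    def test_matches_independent_implementation(self, toy):
        biotite_struc = pytest.importorskip("biotite.structure")
        keys, coords = toy.heavy_atoms()
        arr = biotite_struc.AtomArray(len(keys))
        arr.coord = coords.astype(np.float32)
        for i, (rid, name) in enumerate(keys):
            arr.res_id[i] = rid.position
            arr.atom_name[i] = name
            arr.element[i] = sio.element_of(name)
            arr.res_name[i] = "GLY"
            arr.chain_id[i] = "A"
        vdw = np.array([sm.VDW_RADII[sio.element_of(n)] for _, n in keys])
        reference = biotite_struc.sasa(arr, probe_radius=1.4, point_number=1000,
                                       vdw_radii=vdw)
        ours = sm.compute_sasa(toy)
        mine = np.array([ours.atom_sasa[k] for k in keys])
        assert mine.sum() == pytest.approx(float(np.nansum(reference)), rel=0.01)

    def test_residue_totals_are_atom_sums(self, toy, toy_sasa):
        for res in toy.residues:
            total = sum(toy_sasa.atom_sasa[(res.id, n)] for n in res.atoms)
            assert toy_sasa.residue_sasa[res.id] == pytest.approx(total, abs=1e-9)

    def test_distant_atom_removal_leaves_sasa_unchanged(self):
        near = [(0.0, 0, 0), (3.0, 0, 0)]
        far = (50.0, 0, 0)
        with_far = sm.compute_sasa(single_atom_structure(near + [far]))
        without = sm.compute_sasa(single_atom_structure(near))
        for i in (1, 2):
            assert with_far.atom_sasa[(sio.ImgtId(i), "CA")] == pytest.approx(
                without.atom_sasa[(sio.ImgtId(i), "CA")], abs=1e-12)

    def test_no_atoms_raises(self):
        with pytest.raises((EmptyStructureError, ValueError)):
            sm.compute_sasa(sio.NanobodyStructure([]))

    def test_deterministic(self, toy):
        a = sm.compute_sasa(toy)
        b = sm.compute_sasa(toy)
        assert a.atom_sasa == b.atom_sasa


def three_residue_toy():
    """Three exposed residues (F, R, D) with a couple of atoms each."""
    residues = [
        sio.Residue(sio.ImgtId(105), "F",
                    {"CA": np.array([0.0, 0, 0]), "CB": np.array([0.0, 1.5, 0])}),
        sio.Residue(sio.ImgtId(106), "R",
                    {"CA": np.array([4.0, 0, 0]), "CB": np.array([4.0, 1.5, 0])}),
        sio.Residue(sio.ImgtId(107), "D",
                    {"CA": np.array([8.0, 0, 0]), "CB": np.array([8.0, 1.5, 0])}),
    ]
    return sio.NanobodyStructure(residues)


def brute_force_patches(s, sasa, vicinity, radius=7.5):
    """O(n^2) re-derivation of the three patch scores."""
    psh = ppc = pnc = 0.0
    atoms = []
    for r in s.residues:
        if r.id in vicinity:
            for name, c in r.atoms.items():
                if sasa.atom_sasa[(r.id, name)] > 0:
                    atoms.append((r.id, r.aa, c))
    for (i1, a1, c1), (i2, a2, c2) in itertools.combinations(atoms, 2):
        if i1 == i2:
            continue
        d = np.linalg.norm(c1 - c2)
        if d > radius:
            continue
        psh += sm.hydrophobicity(a1) * sm.hydrophobicity(a2) / d
        if a1 in "RK" and a2 in "RK":
            ppc += 1.0 / d
        if a1 in "DE" and a2 in "DE":
            pnc += 1.0 / d
    return psh, ppc, pnc


class TestCdrVicinity:
    def test_matches_brute_force_distance_scan(self, toy, toy_sasa):
        cutoff, thr = 4.0, 0.075
        vic = sm.cdr_vicinity(toy, toy_sasa, cutoff, thr)
        cdr_ids = {r.id for r in toy.cdr_residues()}
        expected = {i for i in cdr_ids if toy_sasa.relative_sasa[i] >= thr}
        expected |= {sio.ImgtId(104), sio.ImgtId(118)}
        keys, coords = toy.heavy_atoms()
        for i, (rid, _) in enumerate(keys):
            if rid in cdr_ids or rid in expected:
                continue
            if toy_sasa.relative_sasa[rid] < thr:
                continue
            d = min(np.linalg.norm(coords[i] - coords[j])
                    for j, (rj, _) in enumerate(keys) if rj in cdr_ids)
            if d <= cutoff:
                expected.add(rid)
        assert vic == expected

    def test_isolated_cdr_vicinity_is_cdrs_plus_anchors(self):
        # loop-only structure: no framework residue near any CDR atom
        residues = [sio.Residue(sio.ImgtId(104), "C", {"CA": np.array([0.0, 0, 0])}),
                    sio.Residue(sio.ImgtId(110), "F", {"CA": np.array([3.8, 0, 8.0])}),
                    sio.Residue(sio.ImgtId(118), "W", {"CA": np.array([7.6, 0, 0])}),
                    sio.Residue(sio.ImgtId(1), "S", {"CA": np.array([100.0, 0, 0])})]
        s = sio.NanobodyStructure(sorted(residues, key=lambda r: r.id))
        sasa = sm.compute_sasa(s)
        vic = sm.cdr_vicinity(s, sasa)
        assert vic == {sio.ImgtId(110), sio.ImgtId(104), sio.ImgtId(118)}

    def test_buried_cdr_residue_excluded(self, toy, toy_sasa):
        vic = sm.cdr_vicinity(toy, toy_sasa, exposure_threshold=1e9)
        # nothing passes an unattainable exposure threshold: only anchors remain
        assert vic == {sio.ImgtId(104), sio.ImgtId(118)}


class TestPatchScores:
    def test_brute_force_oracle_small_toy(self):
        s = three_residue_toy()
        sasa = sm.compute_sasa(s)
        vic = frozenset(r.id for r in s.residues)
        scores = sm.patch_scores(s, sasa, vic)
        psh, ppc, pnc = brute_force_patches(s, sasa, vic)
        assert scores.psh == pytest.approx(psh, abs=1e-12)
        assert scores.ppc == pytest.approx(ppc, abs=1e-12)
        assert scores.pnc == pytest.approx(pnc, abs=1e-12)
        assert scores.psh > 0

    def test_brute_force_oracle_full_fixture(self, toy, toy_sasa):
        vic = sm.cdr_vicinity(toy, toy_sasa)
        scores = sm.patch_scores(toy, toy_sasa, vic)
        psh, ppc, pnc = brute_force_patches(toy, toy_sasa, vic)
        assert scores.psh == pytest.approx(psh, rel=1e-12)
        assert scores.ppc == pytest.approx(ppc, rel=1e-12)
        assert scores.pnc == pytest.approx(pnc, rel=1e-12)

    def test_rigid_motion_invariance(self, toy, toy_sasa):
        # exposure gating held fixed; pair distances are isometry-invariant
        vic = sm.cdr_vicinity(toy, toy_sasa)
        base = sm.patch_scores(toy, toy_sasa, vic)
        rng = np.random.default_rng(11)
        for _ in range(5):
            moved = toy.transformed(random_rotation(rng), rng.normal(scale=30.0, size=3))
            moved_scores = sm.patch_scores(moved, toy_sasa, vic)
            assert moved_scores.psh == pytest.approx(base.psh, rel=1e-9)
            assert moved_scores.ppc == pytest.approx(base.ppc, rel=1e-9)
            assert moved_scores.pnc == pytest.approx(base.pnc, rel=1e-9)

    def test_no_hydrophobic_pairs_zero_psh(self):
        s = single_atom_structure([(0, 0, 0)], aa="G")
        sasa = sm.compute_sasa(s)
        scores = sm.patch_scores(s, sasa, frozenset({sio.ImgtId(1)}))
        assert scores.psh == scores.ppc == scores.pnc == 0.0

    def test_empty_vicinity_scores_zero(self, toy, toy_sasa):
        scores = sm.patch_scores(toy, toy_sasa, frozenset())
        assert (scores.psh, scores.ppc, scores.pnc) == (0.0, 0.0, 0.0)

    def test_charge_mirror_symmetry(self):
        def charged_pair(aa):
            return sio.NanobodyStructure([
                sio.Residue(sio.ImgtId(105), aa, {"CB": np.array([0.0, 0, 0])}),
                sio.Residue(sio.ImgtId(106), aa, {"CB": np.array([4.0, 0, 0])}),
            ])

        pos = charged_pair("R")
        neg = charged_pair("D")
        vic = frozenset({sio.ImgtId(105), sio.ImgtId(106)})
        sp = sm.patch_scores(pos, sm.compute_sasa(pos), vic)
        sn = sm.patch_scores(neg, sm.compute_sasa(neg), vic)
        assert sp.ppc > 0 and sp.pnc == 0
        assert sn.pnc == pytest.approx(sp.ppc) and sn.ppc == 0

    def test_adding_qualifying_pair_increases_score(self):
        s = three_residue_toy()
        sasa = sm.compute_sasa(s)
        vic_small = frozenset({sio.ImgtId(105), sio.ImgtId(106)})
        vic_full = frozenset(r.id for r in s.residues)
        assert sm.patch_scores(s, sasa, vic_full).psh > sm.patch_scores(s, sasa, vic_small).psh


class TestTetradMotif:
    def test_hallmark_classes(self):
        for tetrad, cls in [("FERG", "VHH-hallmark"), ("VGLW", "VH-like"), ("FGLG", "other")]:
            s = make_toy_nanobody(FixtureSpec(tetrad=tetrad, seed=1))
            motif = sm.tetrad_motif(s)
            assert motif.motif == tetrad
            assert motif.hallmark_class == cls

    def test_missing_position_gap(self):
        s = make_toy_nanobody(FixtureSpec(tetrad="FERG", seed=1))
        partial = sio.NanobodyStructure([r for r in s.residues if r.id.position != 52])
        motif = sm.tetrad_motif(partial)
        assert motif.motif == "FER-"
        assert motif.hallmark_class == "other"


class TestLiabilities:
    def make(self, cdr3_seq):
        return make_toy_nanobody(FixtureSpec(cdr3_length=len(cdr3_seq),
                                             cdr3_seq=cdr3_seq, seed=1))

    def test_surface_deamidation_motif(self):
        s = self.make("YYYYNGYYYYYYY")
        sasa = sm.compute_sasa(s)
        hits = [h for h in sm.detect_liabilities(s, sasa) if h.motif == "NG"]
        assert len(hits) == 1
        assert hits[0].motif_name == "deamidation"
        assert hits[0].surface_exposed  # CDR3 loop apex is maximally exposed

    def test_nps_is_not_a_sequon(self):
        s = self.make("YYYYYNPSYYYYY")
        hits = sm.detect_liabilities(s, sm.compute_sasa(s))
        assert not any(h.motif_name == "glycosylation" for h in hits)
        s2 = self.make("YYYYYNASYYYYY")
        hits2 = sm.detect_liabilities(s2, sm.compute_sasa(s2))
        assert any(h.motif_name == "glycosylation" and h.motif == "NAS" for h in hits2)

    def test_unpaired_cysteine_but_not_conserved_pair(self):
        s = self.make("YYYYYYCYYYYYY")
        hits = sm.detect_liabilities(s, sm.compute_sasa(s))
        cys = [h for h in hits if h.motif_name == "unpaired-cysteine"]
        assert len(cys) == 1
        assert cys[0].positions[0].position not in (23, 104)

    def test_buried_methionine_flagged_not_exposed(self):
        s = make_toy_nanobody(FixtureSpec(seed=1, sequence_overrides={77: "M"}))
        sasa = sm.compute_sasa(s)
        hits = sm.detect_liabilities(s, sasa, exposure_threshold=2.0)
        met = [h for h in hits if h.motif == "M" and h.positions[0].position == 77]
        assert len(met) == 1 and not met[0].surface_exposed
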