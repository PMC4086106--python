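"""Contact detection, distance classes, special positions, markers."""

import numpy as np
import pytest

from structmap import fixtures as fx
from structmap.contacts import (Contact, assign_markers, classify_distance,
                                detect_special_positions,
                                find_assembly_contacts, find_crystal_contacts,
                                ligand_symbol_map, write_contact_tsv)
from structmap.model import symmetry_ops


def brute_force_crystal_contacts(structure, cutoff=5.0):
    """Independent oracle: explicit symmetry copies in all 27 cells,
    all-atom-pairs scan; per-residue minimum image distance."""
    cell = structure.cell
    coords = np.array([a.pos for r in structure.model.residues
                       for a in r.heavy_atoms()])
    keys = [r.key for r in structure.model.residues for _ in r.heavy_atoms()]
    frac = cell.fractionalize(coords)
    best = {}
    for op in symmetry_ops(cell.spacegroup):
        base = frac @ op.rot_array.T + op.trans_array
        for i in range(-1, 2):
            for j in range(-1, 2):
                for k in range(-1, 2):
                    if op.is_identity and i == j == k == 0:
                        continue
                    img = cell.orthogonalize(base + np.array([i, j, k], float))
                    for ai in range(len(coords)):
                        d = np.linalg.norm(img - coords[ai], axis=1).min()
                        if d <= cutoff:
                            best[keys[ai]] = min(best.get(keys[ai], 1e9), d)
    return best


class TestDistanceClasses:
    @pytest.mark.parametrize("d,cls", [
        (2.9, "close"), (3.19, "close"), (3.2, "far"),  # strict < 3.2
        (4.0, "far"), (5.0, "far"),
    ])
    def test_close_far_boundary(self, d, cls):
        assert classify_distance(d) == cls

    def test_cutoff_inclusive_at_five(self):
        st = fx.two_chain_contact_structure(distance=5.0)
        contacts = find_assembly_contacts(st)
        assert contacts and min(c.min_dist for c in contacts) == pytest.approx(5.0)

    def test_beyond_cutoff_excluded(self):
        st = fx.two_chain_contact_structure(distance=5.0 + 1e-6)
        dists = [c.min_dist for c in find_assembly_contacts(st)]
        assert not any(d == pytest.approx(5.0, abs=1e-5) for d in dists)


class TestAssemblyContacts:
    def test_chains_at_known_distance(self):
        st = fx.two_chain_contact_structure(distance=4.2)
        contacts = find_assembly_contacts(st)
        pp = [c for c in contacts if c.kind == "prot_prot"]
        assert pp
        assert min(c.min_dist for c in pp) == pytest.approx(4.2, abs=1e-9)
        assert all(c.dist_class == "far" for c in pp
                   if c.min_dist == pytest.approx(4.2))
        assert not any(c.crystallographic for c in contacts)

    def test_distant_chains_empty(self):
        st = fx.two_chain_contact_structure(distance=6.0)
        pp = [c for c in find_assembly_contacts(st) if c.kind == "prot_prot"]
        assert pp == []

    def test_ligand_contact_close(self):
        st = fx.two_chain_contact_structure(distance=20.0, ligand_distance=2.9)
        pl = [c for c in find_assembly_contacts(st) if c.kind == "prot_lig"]
        assert pl and all(c.partner.startswith("LIG:HEM") for c in pl)
        closest = min(pl, key=lambda c: c.min_dist)
        assert closest.residue == ("A", 3, "")
        assert closest.min_dist == pytest.approx(2.9)
        assert closest.dist_class == "close"

    def test_unkept_het_ignored(self):
        st = fx.two_chain_contact_structure(distance=20.0, ligand_distance=2.9,
                                            ligand_name="XXX")
        pl = [c for c in find_assembly_contacts(st) if c.kind == "prot_lig"]
        assert pl == []

    def test_symmetric_pairs(self):
        st = fx.two_chain_contact_structure(distance=4.2)
        contacts = find_assembly_contacts(st)
        pp = {(c.residue, c.partner): c.min_dist
              for c in contacts if c.kind == "prot_prot"}
        for (res, partner), d in pp.items():
            # mirrored contact exists on the partner chain at equal distance
            back = [dd for (r2, p2), dd in pp.items()
                    if p2 == res[0] and r2[0] == partner]
            assert any(abs(dd - d) < 1e-9 for dd in back)

    def test_brute_force_all_pairs_oracle(self):
        st = fx.two_chain_contact_structure(distance=4.2, ligand_distance=3.0)
        contacts = find_assembly_contacts(st)
        # oracle: explicit double loop over residues and atoms
        model = st.model
        expected = {}
        for r1 in model.residues:
            for r2 in model.residues:
                if r1 is r2 or r1.is_het:
                    continue
                if r2.is_het:
                    kind = "prot_lig"
                elif r1.chain_id != r2.chain_id:
                    kind = "prot_prot"
                else:
                    continue
                d = min(np.linalg.norm(a1.pos - a2.pos)
                        for a1 in r1.heavy_atoms() for a2 in r2.heavy_atoms())
                if d <= 5.0:
                    k = (kind, r1.key)
                    expected[k] = min(expected.get(k, 1e9), d)
        mine = {}
        for c in contacts:
            k = (c.kind, c.residue)
            mine[k] = min(mine.get(k, 1e9), c.min_dist)
        assert set(mine) == set(expected)
        for k in expected:
            assert mine[k] == pytest.approx(expected[k], abs=1e-9)


class TestCrystalContacts:
    @pytest.mark.parametrize("sg,cell_len", [
        ("P 1", 9.0), ("P 21 21 21", 15.0), ("P 2", 13.0), ("C 2", 16.0),
    ])
    def test_matches_27cell_brute_force(self, sg, cell_len):
        st = fx.crystal_structure(sg, cell_len=cell_len, n_res=3)
        contacts, status = find_crystal_contacts(st)
        assert status == "ok" and contacts
        oracle = brute_force_crystal_contacts(st)
        mine = {}
        for c in contacts:
            mine[c.residue] = min(mine.get(c.residue, 1e9), c.min_dist)
        assert set(mine) == set(oracle)
        for k in oracle:
            assert mine[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_random_placements_match_oracle(self, rng):
        for trial in range(5):
            st = fx.crystal_structure("P 21", cell_len=12.0, n_res=2,
                                      offset=rng.uniform(1, 10, 3))
            contacts, _ = find_crystal_contacts(st)
            oracle = brute_force_crystal_contacts(st)
            mine = {}
            for c in contacts:
                mine[c.residue] = min(mine.get(c.residue, 1e9), c.min_dist)
            assert set(mine) == set(oracle)

    def test_no_cell_not_applicable(self):
        st = fx.two_chain_contact_structure()
        contacts, status = find_crystal_contacts(st)
        assert contacts == [] and status == "not applicable"

    def test_zero_cutoff_empty(self):
        st = fx.crystal_structure("P 1", cell_len=10.0)
        contacts, status = find_crystal_contacts(st, cutoff=0.0)
        assert contacts == [] and status == "ok"

    def test_all_flagged_crystallographic(self):
        st = fx.crystal_structure("P 1", cell_len=9.0)
        contacts, _ = find_crystal_contacts(st)
        assert contacts and all(c.crystallographic for c in contacts)


class TestSpecialPositions:
    def test_atom_on_twofold_axis_flagged(self):
        st = fx.special_position_structure(0.0)
        assert detect_special_positions(st) == [("A", 1, "")]

    def test_general_position_not_flagged(self):
        st = fx.special_position_structure(0.0)
        assert ("A", 2, "") not in detect_special_positions(st)

    def test_eps_geometry(self):
        # eps/2 off the axis -> own image at exactly eps -> flagged
        assert ("A", 1, "") in detect_special_positions(
            fx.special_position_structure(0.5), eps=1.0)
        # 2*eps off the axis -> image at 4*eps -> not flagged
        assert ("A", 1, "") not in detect_special_positions(
            fx.special_position_structure(2.0), eps=1.0)

    def test_no_cell_empty(self):
        st = fx.two_chain_contact_structure()
        assert detect_special_positions(st) == []


class TestMarkers:
    def test_crystal_pp_close_is_red_italic_letter(self):
        c = Contact("prot_prot", True, ("A", 5, ""), "A", 3.0)
        ms = assign_markers([], [c], [], [])[("A", 5, "")]
        assert ms.cryst_pp_letter == ("A", "red")

    def test_crystal_pp_far_is_black(self):
        c = Contact("prot_prot", True, ("A", 5, ""), "B", 4.5)
        ms = assign_markers([], [c], [], [])[("A", 5, "")]
        assert ms.cryst_pp_letter == ("B", "black")

    def test_assembly_ligand_close_red_colon_yellow_bg(self):
        c = Contact("prot_lig", False, ("A", 51, ""), "LIG:HEM:A:201", 3.0)
        ms = assign_markers([c], [], [], [])[("A", 51, "")]
        assert ms.assembly_lig_symbols == [(":", "red")]

    def test_crystal_ligand_italic_symbol(self):
        c = Contact("prot_lig", True, ("A", 40, ""), "LIG:HEM:A:201", 4.0)
        ms = assign_markers([], [c], [], [])[("A", 40, "")]
        assert ms.cryst_lig_symbols == [(":", "black")]

    def test_both_contact_types_orange_background(self):
        cc = Contact("prot_prot", True, ("A", 140, ""), "A", 3.0)
        ac = Contact("prot_prot", False, ("A", 140, ""), "B", 4.0)
        ms = assign_markers([ac], [cc], [], [])[("A", 140, "")]
        assert ms.both_orange_background
        assert ms.pp_blue_frame

    def test_orange_requires_both(self):
        cc = Contact("prot_prot", True, ("A", 1, ""), "A", 3.0)
        ms = assign_markers([], [cc], [], [])[("A", 1, "")]
        assert not ms.both_orange_background

    def test_special_position_hash(self):
        ms = assign_markers([], [], [("A", 31, "")], [])[("A", 31, "")]
        assert ms.special_position_hash

    def test_ligand_palette_order_and_recycling(self):
        contacts = [Contact("prot_lig", False, ("A", i, ""),
                            f"LIG:L{i:02d}:A:{200+i}", 4.0)
                    for i in range(10)]
        symbols = ligand_symbol_map(contacts)
        assert symbols["L00"][0] == ":"
        assert symbols["L01"][0] == "^"
        assert len(symbols) == 10
        # 9th compound recycles symbol with numeric legend suffix
        assert symbols["L08"][0] == ":"
        assert "(2)" in symbols["L08"][1]

    def test_pure_function_determinism(self):
        cc = [Contact("prot_prot", True, ("A", 1, ""), "A", 3.0)]
        ac = [Contact("prot_lig", False, ("A", 2, ""), "LIG:HEM:A:9", 2.8)]
        assert assign_markers(ac, cc, [], []) == assign_markers(ac, cc, [], [])


def test_contact_tsv_format():
    c = Contact("prot_lig", True, ("A", 40, ""), "LIG:HEM:A:201", 4.123456)
    text = write_contact_tsv([c])
    lines = text.strip().split("\n")
    assert lines[0].startswith("chain\t")
    assert lines[1] == "A\t40\t\tprot_lig\t1\tLIG:HEM:A:201\t4.123\tfar"
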