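"""Secondary structure, SASA, accessibility, hydropathy, disulfides."""

import numpy as np
import pytest

from structmap import fixtures as fx
from structmap.annotate import (KYTE_DOOLITTLE, annotate_residues,
                                assign_secondary_structure, atom_sasa,
                                classify_accessibility, compute_sasa,
                                detect_disulfides, hydropathy_profile,
                                relative_accessibility, sphere_points)
from structmap.fixtures import make_structure, single_atom_residue
from structmap.model import SSERecord, parse_pdb


class TestSecondaryStructure:
    def test_deposited_helix_record_is_authoritative(self):
        st = fx.helix_structure(12)
        st.helix_sheet_records = [SSERecord("helix", "A", (3, ""), (10, ""))]
        sses = assign_secondary_structure(st)
        helices = [s for s in sses if s.kind == "helix"]
        assert helices == [s for s in sses if s.kind == "helix"]
        assert helices[0].start == (3, "") and helices[0].end == (10, "")

    def test_ideal_helix_detected_geometrically(self, helix):
        sses = assign_secondary_structure(helix)
        helices = [s for s in sses if s.kind == "helix"]
        assert len(helices) == 1
        span = helices[0].end[0] - helices[0].start[0] + 1
        assert span >= 8

    def test_extended_chain_has_no_helix(self, extended):
        sses = assign_secondary_structure(extended)
        assert not any(s.kind == "helix" for s in sses)

    def test_short_chain_all_coil(self):
        st = fx.helix_structure(3)
        assert assign_secondary_structure(st) == []

    def test_antiparallel_sheet_detected(self):
        # two ideal beta strands, second rotated 180 deg and offset into
        # hydrogen-bond register
        a = fx.make_chain(6, -139.0, 135.0, chain_id="A")
        b = fx.make_chain(6, -139.0, 135.0, chain_id="A", start_num=20)
        for r in b:
            for at in r.atoms:
                at.pos = np.diag([-1.0, -1.0, 1.0]) @ at.pos \
                    + np.array([9.0, 6.0, 0.0])
        st = make_structure(a + b)
        sses = assign_secondary_structure(st)
        assert any(s.kind == "strand" for s in sses)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        # carbon r=1.70, probe 1.4 -> 4*pi*3.10^2 = 120.76 A^2
        val = atom_sasa(np.zeros((1, 3)), np.array([1.70]), 1.4, 960)[0]
        assert val == pytest.approx(4 * np.pi * 3.10**2, rel=0.02)

    def test_distant_atoms_are_each_isolated(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        vals = atom_sasa(coords, np.array([1.70, 1.70]), 1.4, 960)
        iso = atom_sasa(np.zeros((1, 3)), np.array([1.70]), 1.4, 960)[0]
        assert vals == pytest.approx([iso, iso])

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_occlusion_matches_high_density_oracle(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([1.70, 1.70])
        vals = atom_sasa(coords, radii, 1.4, 960)
        iso = 4 * np.pi * 3.10**2
        assert vals.sum() < 2 * iso
        # brute-force oracle at 10x point density
        dense = atom_sasa(coords, radii, 1.4, 9600)
        assert vals == pytest.approx(dense, rel=0.02)

    def test_rigid_transform_invariance(self, helix, rng):
        before = compute_sasa(helix, n_points=240)
        moved = fx.perturb_homolog(helix, None, 0.0, seed=7, rigid=True)
        after = compute_sasa(moved, n_points=240)
        for k in before:
            assert after[k] == pytest.approx(before[k], rel=1e-6, abs=1e-6)

    def test_residue_sums_equal_atom_total(self, helix):
        per_res = compute_sasa(helix, n_points=240)
        coords, radii = [], []
        from structmap.annotate import vdw_radius
        for r in helix.model.residues:
            for a in r.heavy_atoms():
                coords.append(a.pos)
                radii.append(vdw_radius(a.element))
        per_atom = atom_sasa(np.array(coords), np.array(radii), 1.4, 240)
        assert sum(per_res.values()) == pytest.approx(per_atom.sum(), abs=1e-9)

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            atom_sasa(np.zeros((1, 3)), np.array([1.7]), -1.0, 960)
        with pytest.raises(ValueError):
            atom_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 50)


class TestAccessibilityClasses:
    @pytest.mark.parametrize("rel,cls", [
        (0.0, "buried"), (0.0999, "buried"), (0.10, "intermediate"),
        (0.25, "intermediate"), (0.3999, "intermediate"),
        (0.40, "accessible"), (1.0, "accessible"),
    ])
    def test_thresholds(self, rel, cls):
        assert classify_accessibility(rel) == cls

    def test_monotone_partition(self):
        grid = np.linspace(0, 1, 101)
        order = {"buried": 0, "intermediate": 1, "accessible": 2}
        ranks = [order[classify_accessibility(x)] for x in grid]
        assert ranks == sorted(ranks)

    def test_unknown_residue_uses_gly_reference(self):
        assert relative_accessibility("XYZ", 52.0) == \
            pytest.approx(relative_accessibility("GLY", 52.0))

    def test_clamped_to_unit(self):
        assert relative_accessibility("GLY", 1e4) == 1.0


class TestHydropathy:
    def test_window_one_is_raw_scale(self):
        prof, cls = hydropathy_profile("ILE"[0] * 5, window=1)
        assert np.allclose(prof, KYTE_DOOLITTLE["I"])
        assert set(cls) == {"hydrophobic"}

    def test_constant_sequence_constant_profile(self):
        prof, _ = hydropathy_profile("AAAAAAAA", window=5)
        assert np.allclose(prof, KYTE_DOOLITTLE["A"])

    def test_alternating_extremes_average_neutral(self):
        seq = "IR" * 10  # I=+4.5, R=-4.5
        prof, cls = hydropathy_profile(seq, window=9)
        # oracle: direct mean over each window
        vals = np.array([KYTE_DOOLITTLE[c] for c in seq])
        for i in range(4, len(seq) - 4):
            assert prof[i] == pytest.approx(vals[i - 4:i + 5].mean())
        assert all(c == "neutral" for c in cls[4:-4])

    def test_terminal_windows_shrink(self):
        seq = "IIIRR"
        prof, _ = hydropathy_profile(seq, window=5)
        vals = [KYTE_DOOLITTLE[c] for c in seq]
        assert prof[0] == pytest.approx(np.mean(vals[:3]))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("AAA", window=4)

    def test_unknown_letter_scored_zero(self):
        prof, _ = hydropathy_profile("Z", window=1)
        assert prof[0] == 0.0


class TestDisulfides:
    def test_geometric_pair_at_bond_distance(self):
        st = fx.cys_pair_structure(2.03)
        assert detect_disulfides(st) == [(("A", 1, ""), ("A", 4, ""))]

    def test_above_cutoff_no_bridge(self):
        st = fx.cys_pair_structure(4.0)
        assert detect_disulfides(st) == []

    def test_ssbond_plus_geometry_no_duplicate(self):
        st = fx.cys_pair_structure(2.03, ssbond=True)
        assert detect_disulfides(st) == [(("A", 1, ""), ("A", 4, ""))]

    def test_ssbond_missing_residue_dropped(self):
        st = fx.cys_pair_structure(4.0)
        st.ssbond_records = [(("A", 1, ""), ("B", 99, ""))]
        assert detect_disulfides(st) == []

    def test_each_cys_in_at_most_one_bridge(self):
        # three cys in a row: closest pair wins, third stays free
        r = [single_atom_residue("A", i, "CYS", "SG", "S", [x, 0, 0])
             for i, x in [(1, 0.0), (2, 2.0), (3, 4.4)]]
        st = make_structure(r)
        bridges = detect_disulfides(st)
        assert bridges == [(("A", 1, ""), ("A", 2, ""))]


class TestAnnotateResidues:
    def test_full_annotation_fields(self):
        st = parse_pdb(fx.five_residue_pdb())
        ann = annotate_residues(st)
        assert len(ann) == 5
        a = ann[("A", 1, "")]
        assert a.ss in ("H", "E", "T", "coil")
        assert a.sasa >= 0 and 0 <= a.rel_acc <= 1
        assert a.acc_class in ("accessible", "intermediate", "buried")
        assert a.hyd_class in ("hydrophobic", "neutral", "hydrophilic")
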