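import numpy as np
import pytest

from varcontext.io import VariantRecord
from varcontext.simulate import build_ideal_coordinates, write_pdb
from varcontext.structure import (
    Atom,
    Residue,
    SsElement,
    StructureModel,
    assign_secondary_structure,
    backbone_hbonds,
    classify_burial,
    classify_variant_site,
    hbond_energy,
    parse_structure,
    shrake_rupley_asa,
    summarize_structure_by_class,
)


def _rotation(theta_deg: float, axis: int = 2) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


class TestParseStructure:
    def test_pdb_round_trip(self, tmp_path):
        model = build_ideal_coordinates("helix", 12)
        path = tmp_path / "helix.pdb"
        write_pdb(model, path)
        parsed = parse_structure(path)
        assert len(parsed) == 12
        assert all(r.complete for r in parsed.residues)
        ca0 = model.residues[0].atom("CA").coord
        ca0_parsed = parsed.residues[0].atom("CA").coord
        assert np.allclose(ca0, ca0_parsed, atol=1e-3)

    def test_plddt_read_from_bfactor(self, tmp_path):
        model = build_ideal_coordinates("helix", 6)
        for atom in model.residues[2].atoms:
            atom.bfactor = 91.2
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        parsed = parse_structure(path)
        assert parsed.residues[2].plddt == pytest.approx(91.2, abs=0.01)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            parse_structure(path)


class TestHydrogenBonds:
    def test_matrix_matches_brute_force_oracle(self):
        # independent recomputation of the Kabsch-Sander energies over all
        # residue pairs, without the distance prefilter
        model = build_ideal_coordinates("helix", 10)
        hb = backbone_hbonds(model)
        res = model.residues
        for d in range(len(res)):
            for a in range(len(res)):
                if abs(d - a) < 2 or d == 0:
                    assert not hb[d, a]
                    continue
                n_d = res[d].atom("N").coord
                c_prev, o_prev = res[d - 1].atom("C").coord, res[d - 1].atom("O").coord
                h_d = n_d + (c_prev - o_prev) / np.linalg.norm(c_prev - o_prev)
                e = hbond_energy(n_d, h_d, res[a].atom("C").coord, res[a].atom("O").coord)
                assert hb[d, a] == (e < -0.5)


class TestSecondaryStructure:
    def test_ideal_helix_h_on_3_to_10(self):
        elements = assign_secondary_structure(build_ideal_coordinates("helix", 12))
        helices = [e for e in elements if e.state == "H"]
        assert helices == [SsElement("H", 3, 10)]

    def test_single_residue_is_coil(self):
        model = build_ideal_coordinates("helix", 12)
        single = StructureModel([model.residues[0]])
        assert assign_secondary_structure(single) == [SsElement("C", 1, 1)]

    def test_antiparallel_pair_interior_is_strand(self):
        model = build_ideal_coordinates("strand_pair", 8)
        elements = assign_secondary_structure(model)
        state = {}
        for el in elements:
            for i in range(el.start, el.end + 1):
                state[i] = el.state
        # interior residues of both strands (indices 3-6 and 13-16)
        for i in list(range(3, 7)) + list(range(13, 17)):
            assert state[i] == "E"

    def test_elements_partition_the_chain(self):
        for kind in ("helix", "strand_pair", "extended"):
            model = build_ideal_coordinates(kind, 10)
            elements = assign_secondary_structure(model)
            covered = sorted(
                i for el in elements for i in range(el.start, el.end + 1)
            )
            assert covered == [r.index for r in model.residues]

    def test_invariant_under_rigid_motion(self):
        model = build_ideal_coordinates("strand_pair", 8)
        rotation = _rotation(73.0, axis=1) @ _rotation(21.0, axis=0)
        moved = model.transformed(rotation, np.array([11.0, -5.0, 3.0]))
        assert assign_secondary_structure(model) == assign_secondary_structure(moved)

    def test_all_incomplete_chain_is_error(self):
        res = Residue(1, "ALA", [Atom("CA", "C", np.zeros(3), 1.7)], complete=False)
        with pytest.raises(ValueError, match="complete backbone"):
            assign_secondary_structure(StructureModel([res]))


def _single_atom_model(radius=1.7):
    return StructureModel([Residue(1, "ALA", [Atom("CA", "C", np.zeros(3), radius)])])


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        asa, _ = shrake_rupley_asa(_single_atom_model(), n_points=960)
        assert asa[0] == pytest.approx(expected, rel=0.02)
        asa_coarse, _ = shrake_rupley_asa(_single_atom_model(), n_points=240)
        assert asa_coarse[0] == pytest.approx(expected, rel=0.05)

    def test_distant_atoms_are_independent(self):
        atoms = [
            Atom("CA", "C", np.zeros(3), 1.7),
            Atom("CA", "C", np.array([100.0, 0, 0]), 1.7),
        ]
        model = StructureModel(
            [Residue(1, "ALA", [atoms[0]]), Residue(2, "ALA", [atoms[1]])]
        )
        asa, _ = shrake_rupley_asa(model)
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert np.allclose(asa, expected, rtol=0.02)

    def test_caged_atom_is_buried(self):
        # icosahedral cage of 12 neighbours at 2.0 Å occludes the center
        phi = (1 + 5**0.5) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = np.array(verts)
        verts = 2.0 * verts / np.linalg.norm(verts[0])
        residues = [Residue(1, "ALA", [Atom("CA", "C", np.zeros(3), 1.7)])]
        for i, v in enumerate(verts, start=2):
            residues.append(Residue(i, "ALA", [Atom("CA", "C", v, 1.7)]))
        asa, _ = shrake_rupley_asa(StructureModel(residues))
        assert asa[0] == pytest.approx(0.0, abs=1e-9)

    def test_asa_non_increasing_as_neighbours_added(self):
        center = Atom("CA", "C", np.zeros(3), 1.7)
        positions = [np.array([3.0, 0, 0]), np.array([0, 3.0, 0]), np.array([0, 0, 3.0])]
        previous = np.inf
        for n_neighbours in range(len(positions) + 1):
            residues = [Residue(1, "ALA", [center])]
            for i, p in enumerate(positions[:n_neighbours], start=2):
                residues.append(Residue(i, "ALA", [Atom("CA", "C", p, 1.7)]))
            asa, _ = shrake_rupley_asa(StructureModel(residues))
            assert asa[0] <= previous + 1e-9
            previous = asa[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            shrake_rupley_asa(_single_atom_model(), n_points=6)


class TestBurial:
    def test_half_max_is_surface(self):
        rsa, burial = classify_burial(52.0, "GLY")  # maxASA(Gly) = 104
        assert rsa == pytest.approx(0.5)
        assert burial == "surface"

    def test_zero_asa_is_interior(self):
        rsa, burial = classify_burial(0.0, "LEU")
        assert rsa == 0.0 and burial == "interior"

    def test_above_max_clipped_to_one(self, caplog):
        with caplog.at_level("WARNING"):
            rsa, burial = classify_burial(500.0, "ALA")
        assert rsa == 1.0 and burial == "surface"

    def test_unknown_residue_type_is_error(self):
        with pytest.raises(ValueError, match="unknown residue"):
            classify_burial(10.0, "XYZ")

    def test_extended_chain_is_all_surface(self):
        model = build_ideal_coordinates("extended", 8)
        _, res_asa = shrake_rupley_asa(model)
        for r in model.residues:
            rsa, burial = classify_burial(res_asa[r.index], r.name)
            assert rsa > 0.25 and burial == "surface"


class TestVariantSite:
    ELEMENTS = [
        SsElement("C", 1, 9),
        SsElement("H", 10, 25),
        SsElement("C", 26, 30),
    ]

    @pytest.mark.parametrize(
        "pos, expected",
        [(10, "boundary"), (12, "boundary"), (17, "middle"), (23, "boundary"),
         (25, "boundary"), (5, "linker")],
    )
    def test_positions(self, pos, expected):
        assert classify_variant_site(pos, self.ELEMENTS, boundary_width=2) == expected

    def test_accepts_variant_record(self):
        v = VariantRecord(gene_id="G1", protein_pos=17, ref_aa="K", alt_aa="R")
        assert classify_variant_site(v, self.ELEMENTS) == "middle"

    def test_uncovered_index_is_error(self):
        with pytest.raises(ValueError, match="not covered"):
            classify_variant_site(99, self.ELEMENTS)


class TestSummary:
    def _ann(self, key, position, burial):
        from varcontext.structure import StructuralAnnotation

        return StructuralAnnotation(
            variant_key=key, ss_state="C" if position == "linker" else "H",
            element_position=position, rsa=0.1, burial=burial, confidence=90.0,
        )

    def test_planted_fractions_recovered_exactly(self):
        annotations, classes = [], {}
        for i in range(10):
            key = ("G1", i + 1, "R", "allofus")
            annotations.append(self._ann(key, "linker", "interior"))
            classes[key] = "disease"
        summary = summarize_structure_by_class(annotations, classes)
        row = summary.iloc[0]
        assert (row["element_position"], row["burial"]) == ("linker", "interior")
        assert row["fraction"] == 1.0 and row["count"] == 10

    def test_empty_input_gives_empty_table(self):
        summary = summarize_structure_by_class([], {})
        assert len(summary) == 0

    def test_unknown_key_is_error(self):
        ann = self._ann(("G9", 1, "R", "cosmic"), "middle", "surface")
        with pytest.raises(ValueError, match="unknown variant key"):
            summarize_structure_by_class([ann], {})
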