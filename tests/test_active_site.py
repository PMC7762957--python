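"""Subsite mapping, contact analytics and displacement classification,
checked against brute-force distance oracles on synthetic fixtures."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from phytomotion.active_site import (
    SelectionError,
    compare_subsites,
    displacement_table,
    find_disulfides,
    map_subsites,
    min_distance,
    polar_contacts,
)
from phytomotion.rigid_geometry import apply
from phytomotion.structure_io import (
    AtomRecord,
    Residue,
    ResidueRef,
    Selection,
    StructureModel,
    extract_ligands,
)
from phytomotion.synthetic_data import (
    SyntheticMotionSpec,
    SyntheticSiteSpec,
    make_ligand_site,
    make_motion_pair,
)

from conftest import random_transform, transform_model


def _site(shells=(), his_subsite=6, his_distance=3.0):
    spec = SyntheticSiteSpec(
        shell_residues=list(shells),
        his_subsite=his_subsite,
        his_distance=his_distance,
    )
    model, gt = make_ligand_site(spec)
    ligand = extract_ligands(model, "IHS")[0]
    return model, ligand, gt


def test_label_order_decreasing_from_scissile_position():
    """His facing ring position 6 puts the axial 2-substituent in pocket E
    (A=6, B=5, C=4, D=3, E=2, F=1)."""
    model, ligand, gt = _site(his_subsite=6)
    smap = map_subsites(model, ligand, gt.catalytic_his)
    assert {lab: e.ring_position for lab, e in smap.entries.items()} == {
        "A": 6, "B": 5, "C": 4, "D": 3, "E": 2, "F": 1,
    }


def test_label_order_wraps_cyclically():
    model, ligand, gt = _site(his_subsite=3)
    smap = map_subsites(model, ligand, gt.catalytic_his)
    assert {lab: e.ring_position for lab, e in smap.entries.items()} == {
        "A": 3, "B": 2, "C": 1, "D": 6, "E": 5, "F": 4,
    }


def test_distant_shell_gives_empty_contact_lists():
    model, ligand, gt = _site(his_distance=9.0)
    smap = map_subsites(model, ligand, gt.catalytic_his, cutoff=6.0)
    assert all(not e.contact_residues for e in smap.entries.values())


def test_planted_residues_recovered_and_boundary_excluded():
    shells = [("ALA", 1, 4.0), ("SER", 3, 5.9), ("GLU", 6, 6.05)]
    model, ligand, gt = _site(shells)
    smap = map_subsites(model, ligand, gt.catalytic_his, cutoff=6.0)
    by_label = {lab: set(smap.contacts(lab)) for lab in "ABCDEF"}
    for ref, label, dist in gt.planted:
        if dist <= 6.0:
            assert ref in by_label[label]
        else:
            assert ref not in by_label[label]


def test_contact_lists_match_brute_force_oracle():
    shells = [("ALA", 2, 5.0), ("LYS", 4, 3.5), ("SER", 4, 5.9)]
    model, ligand, gt = _site(shells)
    smap = map_subsites(model, ligand, gt.catalytic_his, cutoff=6.0)
    lig_res = [r for r in model.het_components if r.name == "IHS"][0]
    lig_ids = {id(a) for a in lig_res.atoms}
    for lab, entry in smap.entries.items():
        gcoords = np.stack([a.coords for a in entry.substituent_atoms])
        expected = set()
        for res in model.residues(het=False):
            acoords = np.stack(
                [a.coords for a in res.atoms if id(a) not in lig_ids]
            )
            if cdist(acoords, gcoords).min() <= 6.0:
                expected.add(res.ref)
        assert set(smap.contacts(lab)) == expected


def test_contact_lists_nest_with_cutoff():
    shells = [("ALA", 1, 4.0), ("SER", 3, 5.5)]
    model, ligand, gt = _site(shells)
    small = map_subsites(model, ligand, gt.catalytic_his, cutoff=4.5)
    large = map_subsites(model, ligand, gt.catalytic_his, cutoff=6.0)
    for lab in "ABCDEF":
        assert set(small.contacts(lab)) <= set(large.contacts(lab))


def test_label_assignment_stable_under_atom_order():
    model, ligand, gt = _site([("ALA", 1, 4.0)])
    shuffled = type(ligand)(
        component_id=ligand.component_id,
        conformer=ligand.conformer,
        ring_atoms=ligand.ring_atoms,
        substituents={
            pos: list(reversed(grp))
            for pos, grp in ligand.substituents.items()
        },
        occupancy=ligand.occupancy,
    )
    a = map_subsites(model, ligand, gt.catalytic_his)
    b = map_subsites(model, shuffled, gt.catalytic_his)
    for lab in "ABCDEF":
        assert a.entries[lab].ring_position == b.entries[lab].ring_position
        assert a.contacts(lab) == b.contacts(lab)


# --- min_distance ----------------------------------------------------------


def _atom(serial, name, element, xyz, res):
    return AtomRecord(serial, name, element, "", 1.0, 10.0, np.array(xyz))


def _point_model():
    r1 = ResidueRef("A", 1, "", "GLY")
    r2 = ResidueRef("A", 2, "", "GLY")
    res1 = Residue(ref=r1, atoms=[_atom(1, "CA", "C", [0, 0, 0], r1)])
    res2 = Residue(ref=r2, atoms=[_atom(2, "CA", "C", [5, 0, 0], r2)])
    return StructureModel(id="pts", chains={"A": [res1, res2]})


def test_min_distance_two_atoms():
    model = _point_model()
    d, (ra, na), (rb, nb) = min_distance(
        model,
        Selection(residue_ranges=[(1, 1)]),
        Selection(residue_ranges=[(2, 2)]),
    )
    assert d == pytest.approx(5.0)
    assert (ra.seq_number, rb.seq_number) == (1, 2)


def test_min_distance_selection_vs_itself_is_zero():
    model = _point_model()
    d, p1, p2 = min_distance(
        model, Selection(residue_ranges=[(1, 1)]),
        Selection(residue_ranges=[(1, 1)]),
    )
    assert d == 0.0
    assert p1 == p2


def test_min_distance_empty_selection_errors():
    model = _point_model()
    with pytest.raises(SelectionError):
        min_distance(
            model, Selection(residue_ranges=[(1, 1)]),
            Selection(residue_ranges=[(9, 9)]),
        )


def _random_atom_model(rng, n=100):
    residues = []
    for i in range(n):
        ref = ResidueRef("A", i + 1, "", "GLY")
        residues.append(
            Residue(
                ref=ref,
                atoms=[
                    AtomRecord(
                        i + 1, "CA", "C", "", 1.0, 10.0,
                        rng.uniform(-20, 20, 3),
                    )
                ],
            )
        )
    return StructureModel(id="rand", chains={"A": residues})


def test_min_distance_matches_exhaustive_scan():
    rng = np.random.default_rng(21)
    model = _random_atom_model(rng)
    sel_a = Selection(residue_ranges=[(1, 50)])
    sel_b = Selection(residue_ranges=[(51, 100)])
    d, _, _ = min_distance(model, sel_a, sel_b)
    coords = np.stack(
        [r.atoms[0].coords for r in model.polymer("A")]
    )
    oracle = cdist(coords[:50], coords[50:]).min()
    assert d == pytest.approx(float(oracle), abs=0.0)


def test_min_distance_invariant_under_rigid_transform():
    rng = np.random.default_rng(22)
    model = _random_atom_model(rng)
    sel_a = Selection(residue_ranges=[(1, 50)])
    sel_b = Selection(residue_ranges=[(51, 100)])
    d0, _, _ = min_distance(model, sel_a, sel_b)
    moved = transform_model(model, random_transform(rng))
    d1, _, _ = min_distance(moved, sel_a, sel_b)
    assert d1 == pytest.approx(d0, abs=1e-9)


# --- disulfides ------------------------------------------------------------


def _cys_pair_model(separation):
    residues = []
    for i, x in enumerate((0.0, separation)):
        ref = ResidueRef("A", 10 * (i + 1), "", "CYS")
        residues.append(
            Residue(
                ref=ref,
                atoms=[
                    AtomRecord(2 * i + 1, "CA", "C", "", 1.0, 10.0,
                               np.array([x, 3.0, 0.0])),
                    AtomRecord(2 * i + 2, "SG", "S", "", 1.0, 10.0,
                               np.array([x, 0.0, 0.0])),
                ],
            )
        )
    return StructureModel(id="cys", chains={"A": residues})


def test_disulfide_found_at_bond_distance():
    records = find_disulfides(_cys_pair_model(2.05))
    assert len(records) == 1
    assert records[0].kind == "disulfide"
    assert records[0].distance == pytest.approx(2.05)
    assert {r.seq_number for r in
            (records[0].partner_1[0], records[0].partner_2[0])} == {10, 20}


def test_no_disulfide_beyond_cutoff():
    assert find_disulfides(_cys_pair_model(3.5)) == []


def test_disulfides_match_brute_force_on_random_field():
    rng = np.random.default_rng(23)
    residues = []
    sg_coords = []
    for i in range(40):
        xyz = rng.uniform(-10, 10, 3)
        sg_coords.append(xyz)
        ref = ResidueRef("A", i + 1, "", "CYS")
        residues.append(
            Residue(ref=ref, atoms=[
                AtomRecord(i + 1, "SG", "S", "", 1.0, 10.0, xyz)
            ])
        )
    model = StructureModel(id="field", chains={"A": residues})
    got = {
        frozenset((r.partner_1[0].seq_number, r.partner_2[0].seq_number))
        for r in find_disulfides(model)
    }
    coords = np.stack(sg_coords)
    d = cdist(coords, coords)
    expected = {
        frozenset((i + 1, j + 1))
        for i in range(40)
        for j in range(i + 1, 40)
        if d[i, j] <= 2.3
    }
    assert got == expected


# --- polar contacts --------------------------------------------------------


def _two_atom_polar_model(elem_a, elem_b, separation):
    r1 = ResidueRef("A", 1, "", "GLY")
    r2 = ResidueRef("B", 1, "", "GLY")
    res1 = Residue(ref=r1, atoms=[
        AtomRecord(1, "O" if elem_a == "O" else "X1", elem_a, "", 1.0, 10.0,
                   np.zeros(3))
    ])
    res2 = Residue(ref=r2, atoms=[
        AtomRecord(2, "O" if elem_b == "O" else "X2", elem_b, "", 1.0, 10.0,
                   np.array([separation, 0.0, 0.0]))
    ])
    return StructureModel(id="polar", chains={"A": [res1], "B": [res2]})


def test_polar_pair_within_cutoff_reported():
    model = _two_atom_polar_model("O", "O", 3.4)
    records = polar_contacts(
        model, Selection(chains=["A"]), Selection(chains=["B"])
    )
    assert len(records) == 1 and records[0].distance == pytest.approx(3.4)


def test_carbon_partner_excluded():
    model = _two_atom_polar_model("C", "O", 3.0)
    assert polar_contacts(
        model, Selection(chains=["A"]), Selection(chains=["B"])
    ) == []


def test_polar_contacts_match_brute_force_oracle():
    rng = np.random.default_rng(24)
    residues = []
    serial = 1
    for i in range(30):
        ref = ResidueRef("A", i + 1, "", "GLY")
        atoms = []
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(
                AtomRecord(serial, name, elem, "", 1.0, 10.0,
                           rng.uniform(-8, 8, 3))
            )
            serial += 1
        residues.append(Residue(ref=ref, atoms=atoms))
    model = StructureModel(id="m30", chains={"A": residues})
    sel_a = Selection(residue_ranges=[(1, 15)])
    sel_b = Selection(residue_ranges=[(16, 30)])
    got = {
        (str(r.partner_1[0]), r.partner_1[1], str(r.partner_2[0]),
         r.partner_2[1])
        for r in polar_contacts(model, sel_a, sel_b)
    }
    expected = set()
    for res_a in model.polymer("A")[:15]:
        for res_b in model.polymer("A")[15:]:
            for aa in res_a.atoms:
                for ab in res_b.atoms:
                    if aa.element in "NO" and ab.element in "NO":
                        if np.linalg.norm(aa.coords - ab.coords) <= 3.5:
                            expected.add(
                                (str(res_a.ref), aa.name, str(res_b.ref),
                                 ab.name)
                            )
    assert got == expected


# --- displacement table ----------------------------------------------------


def test_identical_structures_all_static():
    a, _, gt = make_motion_pair(SyntheticMotionSpec(angle=0.0, seed=30))
    fixed = {r for r, lab in gt.labels.items() if lab == "fixed"}
    table = displacement_table(a, a, fixed)
    assert all(r.displacement_class == "lt2" for r in table.rows)
    assert all(r.ca_displacement == pytest.approx(0.0, abs=1e-9)
               for r in table.rows)


def test_displacements_match_generator_ground_truth():
    a, b, gt = make_motion_pair(SyntheticMotionSpec(angle=20.0, seed=31))
    fixed = {r for r, lab in gt.labels.items() if lab == "fixed"}
    table = displacement_table(a, b, fixed)
    for res in a.polymer("A"):
        ca = res.atom("CA").coords
        if gt.labels[res.ref] == "moving":
            expected = float(
                np.linalg.norm(apply(gt.transform, ca[None, :])[0] - ca)
            )
        else:
            expected = 0.0
        assert table.row(res.ref).ca_displacement == pytest.approx(
            expected, abs=1e-6
        )


def test_displacement_classes_cut_at_two_and_four():
    a, b, gt = make_motion_pair(SyntheticMotionSpec(angle=20.0, seed=31))
    fixed = {r for r, lab in gt.labels.items() if lab == "fixed"}
    table = displacement_table(a, b, fixed)
    for row in table.rows:
        d = row.ca_displacement
        expected = "lt2" if d < 2.0 else ("2to4" if d <= 4.0 else "gt4")
        assert row.displacement_class == expected
    assert {r.displacement_class for r in table.rows} == {"lt2", "2to4", "gt4"}


def test_displacement_requires_fixed_domain():
    a, b, _ = make_motion_pair(SyntheticMotionSpec(angle=10.0, seed=32))
    with pytest.raises(ValueError):
        displacement_table(a, b, set())


# --- subsite comparison ----------------------------------------------------


def test_compare_map_with_itself_has_no_differences():
    model, ligand, gt = _site([("ALA", 1, 4.0), ("SER", 3, 5.0)])
    smap = map_subsites(model, ligand, gt.catalytic_his)
    frame = compare_subsites([smap, smap])
    assert (frame["unique"] == "").all()
    assert (
        frame.groupby("subsite")["n_residues"].nunique() == 1
    ).all()


def test_compare_reports_single_planted_difference():
    base = [("ALA", 1, 4.0)]
    model1, lig1, gt1 = _site(base)
    model2, lig2, gt2 = _site(base + [("LYS", 3, 5.0)])
    m1 = map_subsites(model1, lig1, gt1.catalytic_his)
    m2 = map_subsites(model2, lig2, gt2.catalytic_his)
    frame = compare_subsites([m1, m2])
    extra_ref = str(gt2.planted[1][0])
    label = gt2.planted[1][1]
    row = frame[(frame.subsite == label) & (frame["map"] == 1)].iloc[0]
    assert row["unique"] == extra_ref
    others = frame[(frame.subsite != label) & (frame["unique"] != "")]
    assert others.empty


def test_compare_counts_equal_list_lengths():
    model, ligand, gt = _site([("ALA", 1, 4.0)])
    maps = [map_subsites(model, ligand, gt.catalytic_his) for _ in range(3)]
    frame = compare_subsites(maps)
    for lab in "ABCDEF":
        for i, m in enumerate(maps):
            row = frame[(frame.subsite == lab) & (frame["map"] == i)].iloc[0]
            assert row["n_residues"] == len(m.contacts(lab))
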