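import math

import numpy as np
import pytest

from proteotherm.structure import (
    AtomRecord,
    ReplacementRecord,
    Residue,
    StructureModel,
    VDW_RADII,
    bond_deltas,
    burial_class,
    classification_table,
    classify_replacement,
    read_pdb,
    shrake_rupley_asa,
    summarize_effects,
    volume_delta,
    write_pdb,
)
from proteotherm.synthetic import make_ideal_helix


def _single_atom(radius=1.7, coord=(0, 0, 0), name="CA", res="GLY", index=1):
    return Residue(index=index, name=res, atoms=(
        AtomRecord(name=name, element=name[0], coord=np.array(coord, float),
                   radius=radius),))


class TestBurialClass:
    @pytest.mark.parametrize("asa,expected", [
        (10.0, "buried"), (40.0, "intermediate"), (75.0, "exposed"),
        (20.0, "intermediate"), (60.0, "exposed"), (0.0, "buried"),
    ])
    def test_thresholds(self, asa, expected):
        assert burial_class(asa) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            burial_class(-1.0)


class TestShrakeRupley:
    def test_isolated_carbon_matches_closed_form(self):
        model = StructureModel(residues=(_single_atom(),))
        asa = shrake_rupley_asa(model)[1].asa
        assert asa == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.005)

    def test_fully_occluded_atom_has_zero_asa(self):
        small = _single_atom(radius=1.0, index=1)
        big = _single_atom(radius=6.0, index=2)
        model = StructureModel(residues=(small, big))
        assert shrake_rupley_asa(model)[1].asa == 0.0

    def test_helix_within_2pct_of_biotite_reference(self, helix20, helix20_asa):
        import biotite.structure as bs

        n = sum(len(r.atoms) for r in helix20.residues)
        arr = bs.AtomArray(n)
        i = 0
        for r in helix20.residues:
            for a in r.atoms:
                arr.coord[i] = a.coord
                arr.res_id[i] = r.index
                arr.res_name[i] = r.name
                arr.atom_name[i] = a.name
                arr.element[i] = a.element
                arr.chain_id[i] = "A"
                i += 1
        radii = np.array([VDW_RADII.get(e, 1.7) for e in arr.element])
        ref = bs.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
        for r in helix20.residues:
            ref_res = float(ref[arr.res_id == r.index].sum())
            assert helix20_asa[r.index].asa == pytest.approx(ref_res, rel=0.02)

    def test_helix_ends_more_exposed_than_core(self, helix20_asa):
        assert helix20_asa[1].asa > helix20_asa[10].asa
        assert helix20_asa[20].asa > helix20_asa[10].asa

    def test_rigid_motion_invariance(self, helix20, helix20_asa):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
        moved = StructureModel(residues=tuple(
            Residue(index=r.index, name=r.name, ss=r.ss, atoms=tuple(
                AtomRecord(name=a.name, element=a.element,
                           coord=R @ a.coord + 12.0, radius=a.radius)
                for a in r.atoms))
            for r in helix20.residues))
        asa2 = shrake_rupley_asa(moved)
        for idx in (1, 5, 10, 15, 20):
            # tolerance set by the fixed finite point set under rotation
            assert asa2[idx].asa == pytest.approx(helix20_asa[idx].asa, abs=2.5)

    def test_determinism(self, helix20, helix20_asa):
        again = shrake_rupley_asa(helix20)
        assert all(again[i].asa == helix20_asa[i].asa for i in again)


class TestVolumeDelta:
    def test_identity_and_direction(self):
        assert volume_delta("A", "A") == 0.0
        assert volume_delta("V", "A") < 0  # Val -> Ala shrinks the side chain

    def test_antisymmetry(self):
        for a, b in [("V", "A"), ("G", "W"), ("K", "D")]:
            assert volume_delta(a, b) == -volume_delta(b, a)

    def test_nonstandard_rejected(self):
        with pytest.raises(KeyError):
            volume_delta("X", "A")


def _lys_asp_pair(mutate_to_ala=False):
    """Lysine NZ placed 3.0 A from an aspartate carboxylate oxygen."""
    asp = Residue(index=1, name="ASP", atoms=(
        AtomRecord(name="CA", element="C", coord=np.array([0.0, 0, 0]), radius=1.7),
        AtomRecord(name="OD1", element="O", coord=np.array([1.5, 0, 0]), radius=1.52),
    ))
    if mutate_to_ala:
        second = Residue(index=2, name="ALA", atoms=(
            AtomRecord(name="CA", element="C", coord=np.array([6.0, 0, 0]), radius=1.7),
            AtomRecord(name="CB", element="C", coord=np.array([5.5, 1, 0]), radius=1.7),
        ))
    else:
        second = Residue(index=2, name="LYS", atoms=(
            AtomRecord(name="CA", element="C", coord=np.array([6.0, 0, 0]), radius=1.7),
            AtomRecord(name="NZ", element="N", coord=np.array([4.5, 0, 0]), radius=1.55),
        ))
    return StructureModel(residues=(asp, second))


class TestBondDeltas:
    def test_identical_models_give_zero(self):
        m = _lys_asp_pair()
        assert bond_deltas(m, m, 2) == (0, 0)

    def test_salt_bridge_removal_on_lys_to_ala(self):
        before = _lys_asp_pair()
        after = _lys_asp_pair(mutate_to_ala=True)
        h, e = bond_deltas(before, after, 2)
        assert e == -1

    def test_antisymmetric_under_model_swap(self):
        before = _lys_asp_pair()
        after = _lys_asp_pair(mutate_to_ala=True)
        fwd = bond_deltas(before, after, 2)
        rev = bond_deltas(after, before, 2)
        assert fwd[0] == -rev[0] and fwd[1] == -rev[1]

    def test_missing_side_chain_reports_unknown(self):
        incomplete = StructureModel(residues=(
            _single_atom(res="ASP", index=1),
            Residue(index=2, name="LYS", atoms=(
                AtomRecord(name="CA", element="C", coord=np.array([6.0, 0, 0]),
                           radius=1.7),)),
        ))
        assert bond_deltas(incomplete, incomplete, 2) == (None, None)


def _rec(from_res, to_res, burial, h=None, e=None, ss="C"):
    return ReplacementRecord(position=1, from_res=from_res, to_res=to_res,
                             burial=burial, ss=ss, h_bond_delta=h, elec_delta=e)


class TestClassifyReplacement:
    def test_hydrophobic_gain_at_buried_is_positive(self):
        c = classify_replacement(_rec("K", "I", "buried", h=0, e=0))
        assert not c.conservative and c.effect == "positive"

    def test_hydrophobic_gain_at_exposed_is_negative(self):
        c = classify_replacement(_rec("S", "F", "exposed"))
        assert not c.conservative and c.effect == "negative"

    def test_conservative_bond_addition_is_positive(self):
        c = classify_replacement(_rec("D", "E", "exposed", h=1, e=0))
        assert c.conservative and c.effect == "positive"
        assert "bond-added" in c.rule

    def test_buried_polar_with_new_bond_rescued_to_positive(self):
        c = classify_replacement(_rec("A", "D", "buried", h=0, e=1))
        assert c.effect == "positive" and c.rule == "NC-buried-polar-new-bond"

    def test_charge_introduced_at_exposed_is_positive(self):
        c = classify_replacement(_rec("S", "K", "exposed"))
        assert c.effect == "positive" and c.rule == "NC-charge-at-exposed"

    def test_intermediate_without_bond_info_is_neutral_with_own_rule(self):
        c = classify_replacement(_rec("K", "I", "intermediate"))
        assert c.effect == "neutral" and c.rule == "NC-intermediate-no-info"

    def test_apolar_volume_rules(self):
        assert classify_replacement(_rec("V", "I", "buried")).effect == "positive"
        assert classify_replacement(_rec("F", "A", "buried")).effect == "negative"
        assert classify_replacement(_rec("I", "L", "buried")).effect == "neutral"

    def test_mirrored_context_never_positive_both_ways(self):
        contexts = [("K", "I", "buried"), ("S", "F", "exposed"),
                    ("A", "D", "exposed"), ("V", "N", "buried"),
                    ("Q", "L", "exposed"), ("G", "E", "buried")]
        for a, b, burial in contexts:
            fwd = classify_replacement(_rec(a, b, burial, h=0, e=0))
            rev = classify_replacement(_rec(b, a, burial, h=0, e=0))
            assert not (fwd.effect == "positive" and rev.effect == "positive")

    def test_identity_replacement_rejected(self):
        with pytest.raises(ValueError):
            _rec("A", "A", "buried")


class TestSummary:
    def _fixture(self):
        recs = [
            _rec("K", "I", "buried", h=0, e=0),      # NC positive
            _rec("S", "F", "exposed"),               # NC negative
            _rec("I", "L", "buried"),                # C apolar neutral
            _rec("V", "F", "exposed"),               # C apolar volume up -> positive
            _rec("D", "E", "exposed", h=1, e=0),     # C charged positive
            _rec("S", "K", "exposed", ss="H"),       # NC positive (charge at surface)
            _rec("N", "Q", "buried", h=0, e=0),      # C polar neutral
            _rec("K", "S", "exposed"),               # charged -> polar at surface
            _rec("L", "D", "buried", h=0, e=0),      # NC negative (charge buried)
            _rec("T", "A", "intermediate"),          # NC neutral (no info)
        ]
        return [classify_replacement(r) for r in recs]

    def test_hand_tally(self):
        cls = self._fixture()
        summary = summarize_effects(cls)
        assert summary["total"] == 10
        assert summary["n_conservative"] == 4
        assert summary["n_non_conservative"] == 6
        effects = [c.effect for c in cls]
        assert effects.count("positive") == 4
        assert effects.count("negative") == 2
        assert effects.count("neutral") == 4
        # K gained at position 6, K lost at position 8 -> net 0
        assert summary["net_exposed_positive_charge"] == 0
        assert summary["secondary_structure_of_positive"]["H"] == 1

    def test_totals_conserved(self):
        cls = self._fixture()
        summary = summarize_effects(cls)
        total = sum(sum(v.values()) for v in summary["counts"].values())
        assert total == summary["total"]

    def test_single_category_input(self):
        cls = [classify_replacement(_rec("I", "L", "buried"))]
        summary = summarize_effects(cls)
        assert summary["counts"]["conservative-hydrophobic"]["neutral"] == 1

    def test_table_has_rule_ids(self):
        table = classification_table(self._fixture())
        assert table["rule"].notna().all()
        assert len(table) == 10


class TestPDBIO:
    def test_round_trip(self, tmp_path, helix20):
        p = tmp_path / "h.pdb"
        write_pdb(helix20, p)
        back = read_pdb(p)
        assert len(back.residues) == len(helix20.residues)
        assert back.residues[0].ss == "H"
        for ra, rb in zip(helix20.residues, back.residues):
            assert ra.name == rb.name
            for a, b in zip(ra.atoms, rb.atoms):
                assert np.allclose(a.coord, b.coord, atol=1e-3)

    def test_missing_atoms_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_pdb(p)
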