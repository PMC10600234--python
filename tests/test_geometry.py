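"""Interface geometry: contacts, superposition, interface RMSD, ΔCOM."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepbinder.geometry import (
    contact_density,
    contact_pairs,
    delta_com,
    interface_rmsd,
    receptor_if_distance,
    superpose_receptor,
    RigidTransform,
)
from pepbinder.structures import Chain, ComplexPair, Residue, Structure, effective_cb

from conftest import random_complex, random_rigid_transform, transform_complex


def brute_force_pairs(pair, cutoff=8.0):
    """Exhaustive O(n*m) double loop over effective-Cβ distances."""
    out = set()
    for r in pair.receptor.residues:
        for b in pair.binder.residues:
            if np.linalg.norm(effective_cb(r) - effective_cb(b)) <= cutoff:
                out.add((r.index, b.index))
    return out


def two_residue_complex(distance):
    """Receptor-binder pair whose only Cβ-Cβ distance is ``distance``."""
    def res(index, x):
        return Residue(index=index, aa="A",
                       atoms={"CA": [x, 1.5, 0], "CB": [x, 0, 0]}, plddt=90)

    rec = Chain("A", [res(1, 0.0), res(2, 100.0), res(3, 200.0)])
    bind = Chain("B", [res(1, distance)])
    return ComplexPair(Structure([rec, bind]), "A", "B")


class TestContactPairs:
    def test_separated_chains_give_empty_interface(self, rng):
        pair = random_complex(rng, separation=500.0)
        iface = contact_pairs(pair)
        assert iface.pairs == []
        assert not iface.receptor_interface and not iface.binder_interface

    @pytest.mark.parametrize("distance, expected", [(7.9, 1), (8.0, 1), (8.1, 0)])
    def test_cutoff_is_inclusive(self, distance, expected):
        iface = contact_pairs(two_residue_complex(distance))
        assert iface.n_contacts == expected

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            pair = random_complex(rng, receptor_len=10, binder_len=6,
                                  separation=rng.uniform(2, 12))
            iface = contact_pairs(pair)
            got = {(p.receptor_residue, p.binder_residue) for p in iface.pairs}
            assert got == brute_force_pairs(pair)
            # interface sets are exactly the projections of the pair list
            assert iface.receptor_interface == {p.receptor_residue for p in iface.pairs}
            assert iface.binder_interface == {p.binder_residue for p in iface.pairs}

    def test_symmetric_under_role_swap(self, rng):
        pair = random_complex(rng, separation=5.0)
        swapped = ComplexPair(pair.structure, pair.binder_chain, pair.receptor_chain)
        fwd = {(p.receptor_residue, p.binder_residue) for p in contact_pairs(pair).pairs}
        rev = {(p.binder_residue, p.receptor_residue) for p in contact_pairs(swapped).pairs}
        assert fwd == rev

    def test_recorded_distances_are_within_cutoff(self, rng):
        pair = random_complex(rng, separation=6.0)
        iface = contact_pairs(pair)
        assert all(p.cb_distance <= iface.cutoff for p in iface.pairs)


class TestContactDensity:
    @pytest.mark.parametrize("n_pairs, length, expected", [(0, 10, 0.0), (25, 10, 2.5)])
    def test_direct_ratio(self, n_pairs, length, expected, rng):
        from pepbinder.geometry import ContactPair, InterfaceDefinition

        pairs = [ContactPair(i, i, 5.0) for i in range(n_pairs)]
        iface = InterfaceDefinition(cutoff=8.0, pairs=pairs)
        assert contact_density(iface, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        from pepbinder.geometry import InterfaceDefinition

        with pytest.raises(ValueError):
            contact_density(InterfaceDefinition(cutoff=8.0, pairs=[]), 0)


class TestSuperposeReceptor:
    def test_identity_on_self(self, rng):
        pair = random_complex(rng)
        frame = superpose_receptor(pair, pair)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(frame.translation, 0, atol=1e-9)

    def test_recovers_known_transform(self, rng):
        native = random_complex(rng)
        rot, trans = random_rigid_transform(rng)
        predicted = transform_complex(native, rot, trans)
        frame = superpose_receptor(native, predicted)
        pred_ca = predicted.receptor.ca_coords()
        nat_ca = native.receptor.ca_coords()
        rmsd = np.sqrt(np.mean(np.sum((frame.apply(pred_ca) - nat_ca) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_mirror_image_stays_proper_rotation(self, rng):
        native = random_complex(rng)
        mirror = transform_complex(native, np.eye(3), np.zeros(3))
        for chain in mirror.structure.chains:
            for res in chain.residues:
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] * np.array([-1.0, 1.0, 1.0])
        frame = superpose_receptor(native, mirror)
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)
        pred_ca = frame.apply(mirror.receptor.ca_coords())
        rmsd = np.sqrt(np.mean(np.sum((pred_ca - native.receptor.ca_coords()) ** 2, axis=1)))
        assert rmsd > 1.0

    def test_too_few_pairable_residues_rejected(self, rng):
        small = random_complex(rng, receptor_len=2)
        with pytest.raises(ValueError):
            superpose_receptor(small, small)

    def test_least_squares_beats_random_transforms(self, rng):
        native = random_complex(rng)
        rot, trans = random_rigid_transform(rng)
        predicted = transform_complex(native, rot, trans)
        frame = superpose_receptor(native, predicted)
        nat_ca = native.receptor.ca_coords()
        pred_ca = predicted.receptor.ca_coords()
        best = np.sqrt(np.mean(np.sum((frame.apply(pred_ca) - nat_ca) ** 2, axis=1)))
        for _ in range(20):
            r2, t2 = random_rigid_transform(rng)
            other = np.sqrt(np.mean(np.sum((pred_ca @ r2.T + t2 - nat_ca) ** 2, axis=1)))
            assert best <= other + 1e-9


class TestInterfaceRMSD:
    def test_identity_gives_zero(self, rng):
        pair = random_complex(rng, separation=5.0)
        assert interface_rmsd(pair, pair) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binder_translation(self, rng):
        native = random_complex(rng, separation=5.0)
        shifted = transform_complex(native, np.eye(3), np.zeros(3))
        for res in shifted.binder.residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([1.5, 0, 0])
        assert interface_rmsd(native, shifted) == pytest.approx(1.5, abs=1e-9)

    def test_invariant_under_joint_rigid_transform(self, rng):
        native = random_complex(rng, separation=5.0)
        shifted = transform_complex(native, np.eye(3), np.zeros(3))
        for res in shifted.binder.residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([0.8, -0.6, 0.2])
        base = interface_rmsd(native, shifted)
        rot, trans = random_rigid_transform(rng)
        moved = transform_complex(shifted, rot, trans)
        assert interface_rmsd(native, moved) == pytest.approx(base, abs=1e-6)

    def test_empty_native_interface_rejected(self, rng):
        far = random_complex(rng, separation=500.0)
        with pytest.raises(ValueError):
            interface_rmsd(far, far)


class TestDeltaCOM:
    def test_identity(self, rng):
        pair = random_complex(rng)
        frame = RigidTransform.identity()
        assert delta_com(pair.binder, pair.binder, frame) == pytest.approx(0.0)

    def test_three_four_five_translation(self, rng):
        pair = random_complex(rng)
        shifted = transform_complex(pair, np.eye(3), np.array([3.0, 4.0, 0.0]))
        d = delta_com(shifted.binder, pair.binder, RigidTransform.identity())
        assert d == pytest.approx(5.0, abs=1e-9)

    def test_matches_centroid_oracle(self, rng):
        a = random_complex(rng).binder
        b = random_complex(rng).binder
        rot, trans = random_rigid_transform(rng)
        frame = RigidTransform(rot, trans)
        got = delta_com(a, b, frame)
        ca_a = np.array([r.atoms["CA"] for r in a.residues])
        ca_b = np.array([r.atoms["CA"] for r in b.residues])
        cen_a = (ca_a @ rot.T + trans).sum(axis=0) / len(ca_a)
        cen_b = ca_b.sum(axis=0) / len(ca_b)
        assert got == pytest.approx(np.linalg.norm(cen_a - cen_b), abs=1e-9)


class TestReceptorIfDistance:
    def test_coincident_atoms_give_zero(self, rng):
        pair = random_complex(rng)
        targets = {r.index for r in pair.receptor.residues[:2]}
        clone = Chain("B", [
            Residue(index=i + 1, aa="A", atoms=dict(res.atoms), plddt=50)
            for i, res in enumerate(pair.receptor.residues[:2])
        ])
        assert receptor_if_distance(pair.receptor, targets, clone) == pytest.approx(0.0)

    def test_single_atom_distance(self):
        rec = Chain("A", [Residue(index=1, aa="A", atoms={"CA": [0, 0, 0]}, plddt=50)])
        bind = Chain("B", [Residue(index=1, aa="A", atoms={"CA": [6, 0, 0]}, plddt=50)])
        assert receptor_if_distance(rec, {1}, bind) == pytest.approx(6.0)

    def test_matches_exhaustive_double_loop(self, rng):
        pair = random_complex(rng, separation=6.0)
        targets = {r.index for r in pair.receptor.residues[::2]}
        got = receptor_if_distance(pair.receptor, targets, pair.binder)
        minima = []
        for idx in sorted(targets):
            res = pair.receptor.residue_by_index(idx)
            for xyz in res.atoms.values():
                best = min(
                    np.linalg.norm(xyz - b_xyz)
                    for b_res in pair.binder.residues
                    for b_xyz in b_res.atoms.values()
                )
                minima.append(best)
        assert got == pytest.approx(np.mean(minima), abs=1e-9)

    def test_empty_target_set_rejected(self, rng):
        pair = random_complex(rng)
        with pytest.raises(ValueError):
            receptor_if_distance(pair.receptor, set(), pair.binder)


def test_rigid_transform_rejects_reflection():
    reflect = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        RigidTransform(reflect, np.zeros(3))
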