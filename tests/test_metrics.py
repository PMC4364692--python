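import numpy as np
import pytest

from helixforge.geometry import RigidTransform, Screw
from helixforge.metrics import (
    ContactSet,
    VDW_RADII,
    buried_surface,
    contacts,
    fir,
    fnat,
    groove_width,
    rmsd,
    sasa,
    total_sasa,
)
from helixforge.structures import RegionSpec, Structure


def atoms(coords, res_ids=None, names=None, elements=None, chain="A"):
    coords = np.asarray(coords, float)
    n = len(coords)
    res_ids = res_ids if res_ids is not None else list(range(1, n + 1))
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    return Structure(
        np.array(names), np.array(elements), np.array(res_ids),
        np.array([""] * n), np.array(["ALA"] * n), np.array([chain] * n),
        coords,
    )


def shifted(s, dz):
    return s.transformed(RigidTransform(np.eye(3), np.array([0.0, 0.0, dz])))


class TestContacts:
    def test_far_apart_empty(self, blob40):
        assert len(contacts(blob40, shifted(blob40, 500.0))) == 0

    def test_pair_below_cutoff(self):
        a = atoms([[0, 0, 0]], res_ids=[3])
        b = atoms([[0, 0, 4.9]], res_ids=[8])
        cs = contacts(a, b, cutoff=5.0)
        assert ((3, ""), (8, "")) in cs.pairs
        assert len(contacts(a, b, cutoff=4.8)) == 0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = atoms(rng.uniform(0, 40, (200, 3)))
            b = atoms(rng.uniform(0, 40, (200, 3)))
            fast = contacts(a, b)
            slow = contacts(a, b, brute_force=True)
            assert fast.pairs == slow.pairs

    def test_invalid_cutoff(self, blob40):
        with pytest.raises(ValueError):
            contacts(blob40, blob40, cutoff=0.0)


class TestFnatFir:
    def make_sets(self):
        ref = ContactSet(frozenset({((1, ""), (10, "")), ((2, ""), (11, "")),
                                    ((3, ""), (12, "")), ((4, ""), (13, ""))}))
        half = ContactSet(frozenset({((1, ""), (10, "")), ((2, ""), (11, "")),
                                     ((9, ""), (19, ""))}))
        return ref, half

    def test_identity(self):
        ref, _ = self.make_sets()
        assert fnat(ref, ref) == 1.0
        assert fir(ref, ref) == 1.0
        assert fir(ref, ref, "ligand") == 1.0

    def test_partial_overlap(self):
        ref, half = self.make_sets()
        assert fnat(ref, half) == pytest.approx(0.5)
        assert fir(ref, half) == pytest.approx(0.5)

    def test_disjoint(self):
        ref, _ = self.make_sets()
        other = ContactSet(frozenset({((7, ""), (20, ""))}))
        assert fnat(ref, other) == 0.0
        assert fir(ref, other) == 0.0

    def test_empty_reference(self):
        empty = ContactSet(frozenset())
        ref, _ = self.make_sets()
        with pytest.raises(ValueError):
            fnat(empty, ref)
        with pytest.raises(ValueError):
            fir(empty, ref)

    def test_monotone_under_pair_removal(self):
        ref, _ = self.make_sets()
        pairs = sorted(ref.pairs)
        prev = 1.0
        test = set(pairs)
        for p in pairs:
            test.discard(p)
            if not test:
                break
            val = fnat(ref, ContactSet(frozenset(test)))
            assert val <= prev
            prev = val


class TestRmsd:
    def test_identity(self, blob40):
        assert rmsd(blob40, blob40) == pytest.approx(0.0, abs=1e-9)

    def test_ligand_mode_known_displacement(self, blob40):
        rec = blob40
        lig_ref = shifted(blob40, 25.0)
        # test dimer: same receptor, ligand displaced 3 A further
        lig_test = shifted(blob40, 28.0)
        val = rmsd((rec, lig_ref), (rec, lig_test), mode="ligand")
        assert val == pytest.approx(3.0, abs=1e-6)

    def test_ligand_mode_invariant_to_global_motion(self, blob40, rng):
        from conftest import random_screw

        rec, lig_a = blob40, shifted(blob40, 25.0)
        lig_b = shifted(blob40, 30.0)
        v0 = rmsd((rec, lig_a), (rec, lig_b), mode="ligand")
        g = random_screw(rng).to_transform()
        v1 = rmsd((rec.transformed(g), lig_a.transformed(g)),
                  (rec, lig_b), mode="ligand")
        assert v1 == pytest.approx(v0, abs=1e-6)

    def test_interface_mode_subsets(self, blob40):
        rec, lig = blob40, shifted(blob40, 20.0)
        cs = contacts(rec, lig)
        if len(cs) == 0:
            pytest.skip("no interface in this fixture geometry")
        val = rmsd((rec, lig), (rec, shifted(blob40, 22.0)),
                   mode="interface", reference_interface=cs)
        assert val == pytest.approx(2.0, abs=1e-6)


class TestSasa:
    def test_isolated_atom_sphere(self):
        s = atoms([[0, 0, 0]])
        area = total_sasa(s)
        expect = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area == pytest.approx(expect, rel=1e-6)

    def test_overlap_reduces_area(self):
        pair = atoms([[0, 0, 0], [0, 0, 2.0]])
        lone = atoms([[0, 0, 0]])
        assert total_sasa(pair) < 2 * total_sasa(lone)

    def test_buried_atom_zero(self):
        # central atom fully caged by 12 neighbors at 2 A
        phi = np.pi * (1 + np.sqrt(5))
        i = np.arange(12) + 0.5
        shell = 2.0 * np.column_stack([
            np.sin(np.arccos(1 - 2 * i / 12)) * np.cos(phi * i),
            np.sin(np.arccos(1 - 2 * i / 12)) * np.sin(phi * i),
            1 - 2 * i / 12,
        ])
        s = atoms(np.vstack([[0, 0, 0], shell]))
        areas = sasa(s)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_refinement_oracle(self, rng):
        # low-density result within 1% of a much denser sampling
        for _ in range(3):
            cluster = atoms(rng.uniform(0, 6, (10, 3)))
            coarse = total_sasa(cluster, n_points=960)
            fine = total_sasa(cluster, n_points=10000)
            assert abs(coarse - fine) / fine < 0.01

    def test_unknown_element(self):
        s = atoms([[0, 0, 0]], elements=["XX"])
        with pytest.raises(KeyError):
            sasa(s)


class TestBuriedSurface:
    def test_far_apart_zero(self, blob40):
        out = buried_surface(blob40, shifted(blob40, 300.0), n_points=240)
        assert out["A"]["total"] == pytest.approx(0.0, abs=1e-6)
        assert out["B"]["total"] == pytest.approx(0.0, abs=1e-6)

    def test_contact_buries_area(self, blob40):
        out = buried_surface(blob40, shifted(blob40, 18.0), n_points=240)
        assert out["A"]["total"] > 50.0
        assert out["B"]["total"] > 50.0

    def test_c2_dimer_half_interfaces_equal(self, blob40):
        from scipy.spatial.transform import Rotation

        # B = A rotated 180 deg about x and pushed along z: the dimer has
        # exact C2 symmetry, so the half-interfaces must match
        R = Rotation.from_euler("x", 180, degrees=True).as_matrix()
        lig = blob40.transformed(
            RigidTransform(R, np.array([0.0, 0.0, 14.0])))
        out = buried_surface(blob40, lig, n_points=480)
        assert out["A"]["total"] > 50.0
        diff = abs(out["A"]["total"] - out["B"]["total"])
        assert diff / max(out["A"]["total"], out["B"]["total"]) < 0.05

    def test_region_additivity(self, blob40):
        regions = RegionSpec({"nter": [(1, 10)], "loop": [(20, 25)]})
        out = buried_surface(blob40, shifted(blob40, 18.0), regions,
                             n_points=240)
        for side in ("A", "B"):
            parts = out[side]["nter"] + out[side]["loop"] + out[side]["core"]
            assert parts == pytest.approx(out[side]["total"], abs=1e-6)


def helical_ribbon(pitch, band, n_turns=3, r0=12.0, r1=20.0):
    """Synthetic ribbon: a helical band of atoms with an engineered axial
    gap of (pitch - band) between successive turns."""
    coords = []
    for ang in np.arange(0.0, 360.0 * n_turns, 3.0):
        for rho in np.arange(r0, r1 + 0.1, 1.5):
            for w in np.arange(0.0, band + 0.01, 1.2):
                coords.append([
                    rho * np.cos(np.radians(ang)),
                    rho * np.sin(np.radians(ang)),
                    pitch * ang / 360.0 + w,
                ])
    return atoms(np.array(coords))


class TestGrooveWidth:
    def test_solid_cylinder_no_groove(self):
        z, ang, rho = np.meshgrid(
            np.arange(0.0, 60.0, 2.0),
            np.radians(np.arange(0.0, 360.0, 5.0)),
            np.arange(10.0, 20.1, 2.0),
        )
        coords = np.column_stack([
            (rho * np.cos(ang)).ravel(),
            (rho * np.sin(ang)).ravel(),
            z.ravel(),
        ])
        solid = atoms(coords)
        axis = Screw(np.zeros(3), [0, 0, 1], 60.0, 10.0)
        prof = groove_width(solid, axis, angle_step_deg=5.0)
        assert np.median(prof.width_mean) < 2.0

    def test_engineered_gap(self):
        pitch, band = 20.0, 4.6
        ribbon = helical_ribbon(pitch, band)
        axis = Screw(np.zeros(3), [0, 0, 1], 60.0, pitch / 6.0)
        prof = groove_width(ribbon, axis, angle_step_deg=5.0,
                            atom_radius=1.7)
        engineered = pitch - band - 2 * 1.7
        mid = prof.width_mean[prof.width_mean > 0]
        assert np.median(mid) == pytest.approx(engineered, abs=1.0)

    def test_wider_band_narrower_groove(self):
        axis = Screw(np.zeros(3), [0, 0, 1], 60.0, 20.0 / 6.0)
        narrow = groove_width(helical_ribbon(20.0, 8.0), axis,
                              angle_step_deg=10.0)
        wide = groove_width(helical_ribbon(20.0, 3.0), axis,
                            angle_step_deg=10.0)
        assert (np.median(wide.width_mean[wide.width_mean > 0])
                > np.median(narrow.width_mean[narrow.width_mean > 0]))
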