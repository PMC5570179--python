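import numpy as np
import pytest
from helpers import make_peptide

from pocketdyn.binding_site import define_site_from_point, map_site_residues
from pocketdyn.io_formats import StructureEnsemble
from pocketdyn.superpose import (SuperpositionError, kabsch, per_residue_rmsd,
                                 per_residue_rmsd_stats, site_rmsd,
                                 superpose_member)


def rotation_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture()
def cloud(rng):
    return rng.standard_normal((12, 3)) * 4.0


class TestKabsch:
    def test_identical_points(self, cloud):
        transform, rmsd = kabsch(cloud, cloud)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_pure_translation(self, cloud):
        _, rmsd = kabsch(cloud, cloud + np.array([5.0, 5.0, 5.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_rotation_matches_independent_oracle(self, cloud, rng):
        from scipy.spatial.transform import Rotation

        rot = rotation_z(np.pi / 2)
        noise = rng.standard_normal(cloud.shape) * 0.1
        b = cloud @ rot.T + noise
        transform, rmsd = kabsch(cloud, b)
        # independent oracle: scipy's least-squares rotation fit on the
        # centered clouds gives the same optimal residual
        a_c = cloud - cloud.mean(axis=0)
        b_c = b - b.mean(axis=0)
        best, _ = Rotation.align_vectors(a_c, b_c)
        expected = np.sqrt(np.mean(np.sum((best.apply(b_c) - a_c) ** 2, axis=1)))
        assert rmsd == pytest.approx(expected, abs=1e-9)
        assert np.allclose(transform.rotation, best.as_matrix(), atol=1e-7)
        # optimal fit cannot beat the noise magnitude by construction
        assert 0.0 < rmsd <= np.sqrt(np.mean(np.sum(noise ** 2, axis=1))) + 1e-12

    def test_exact_rotation_recovered_to_1e6(self, cloud):
        rot = rotation_z(0.7)
        b = cloud @ rot.T
        transform, rmsd = kabsch(cloud, b)
        assert rmsd <= 1e-6
        assert np.max(np.abs(transform.rotation - rot.T)) <= 1e-6

    def test_common_rigid_transform_invariance(self, cloud):
        rot = rotation_z(1.1)
        shift = np.array([3.0, -2.0, 7.0])
        _, rmsd_a = kabsch(cloud, cloud * 1.0 + np.array([1.0, 0.0, 0.0]))
        moved_a = cloud @ rot.T + shift
        moved_b = (cloud + np.array([1.0, 0.0, 0.0])) @ rot.T + shift
        _, rmsd_b = kabsch(moved_a, moved_b)
        assert rmsd_a == pytest.approx(rmsd_b, abs=1e-9)

    def test_reflection_corrected(self, cloud):
        mirrored = cloud * np.array([-1.0, 1.0, 1.0])
        transform, _ = kabsch(cloud, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(SuperpositionError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


NAMES = ["ALA", "SER", "LEU", "VAL", "THR", "PHE", "ALA", "GLY"]


@pytest.fixture()
def peptide_pair():
    ref = make_peptide(NAMES, structure_id="ref")
    member = make_peptide(NAMES, structure_id="member")
    site = define_site_from_point(ref, ref.atoms[0].coords, radius=1000.0)
    mapping = map_site_residues(site, ref, member)
    return ref, member, site, mapping


class TestSuperposeMember:
    def test_rigidly_displaced_copy_fits_exactly(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        rot = rotation_z(0.9)
        moved = member.transformed(rot, np.array([4.0, -1.0, 2.0]))
        fitted, rmsd = superpose_member(moved, ref, site, mapping)
        assert rmsd <= 1e-6
        assert np.allclose(fitted.coords(), ref.coords(), atol=1e-6)

    def test_idempotent(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        moved = member.transformed(rotation_z(0.4), np.array([1.0, 2.0, 3.0]))
        fitted, _ = superpose_member(moved, ref, site, mapping)
        refitted, rmsd2 = superpose_member(fitted, ref, site, mapping)
        assert rmsd2 <= 1e-9
        assert np.allclose(refitted.coords(), fitted.coords(), atol=1e-9)

    def test_sidechain_motion_invisible_to_backbone_fit(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        for atom in member.atoms:
            if atom.name == "CB":
                atom.coords = atom.coords + np.array([0.0, 2.0, 1.0])
        fitted, backbone_rmsd = superpose_member(member, ref, site, mapping)
        assert backbone_rmsd <= 1e-9
        assert site_rmsd(fitted, ref, site, mapping, metric="backbone") <= 1e-9
        assert site_rmsd(fitted, ref, site, mapping, metric="sidechain_center") > 0.5


class TestSiteRmsd:
    def test_identical_structures_zero_both_metrics(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        for metric in ("backbone", "sidechain_center"):
            assert site_rmsd(member, ref, site, mapping, metric=metric) == pytest.approx(0.0, abs=1e-12)

    def test_glycine_center_uses_heavy_backbone(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        # displace GLY residue 8 (no side chain) rigidly by 2 A along x
        for atom in member.atoms:
            if atom.residue_key.res_seq == 8:
                atom.coords = atom.coords + np.array([2.0, 0.0, 0.0])
        per_res = per_residue_rmsd(member, ref, site, mapping, metric="sidechain_center")
        assert per_res[("A", 8, "")] == pytest.approx(2.0, abs=1e-12)

    def test_uniform_backbone_displacement_gives_exact_rmsd(self, peptide_pair):
        ref, member, site, mapping = peptide_pair
        for atom in member.atoms:
            if atom.residue_key.res_seq == 3 and atom.name in ("N", "CA", "C", "O"):
                atom.coords = atom.coords + np.array([2.0, 0.0, 0.0])
        per_res = per_residue_rmsd(member, ref, site, mapping, metric="backbone")
        assert per_res[("A", 3, "")] == pytest.approx(2.0, abs=1e-12)
        # pooled site RMSD: sqrt(4 atoms * 2^2 / 32 atoms) = sqrt(0.5)
        pooled = site_rmsd(member, ref, site, mapping, metric="backbone")
        assert pooled == pytest.approx(np.sqrt(4 * 4.0 / 32), abs=1e-12)


class TestPerResidueStats:
    def _ensemble(self, displacements):
        ref = make_peptide(NAMES, structure_id="ref")
        members = []
        for m, disp in enumerate(displacements):
            member = make_peptide(NAMES, structure_id=f"m{m}")
            for atom in member.atoms:
                shift = disp.get(atom.residue_key.res_seq)
                if shift is not None:
                    atom.coords = atom.coords + np.asarray(shift)
            members.append(member)
        site = define_site_from_point(ref, ref.atoms[0].coords, radius=1000.0)
        mappings = [map_site_residues(site, ref, mm) for mm in members]
        return StructureEnsemble(reference=ref, members=members), site, mappings

    def test_identical_copies_all_zero(self):
        ensemble, site, mappings = self._ensemble([{}, {}, {}])
        matrix, means, maxima = per_residue_rmsd_stats(ensemble, site, mappings)
        assert np.all(matrix == 0.0)
        assert np.all(means == 0.0)
        assert all(v == 0.0 for v in maxima.values())

    def test_single_flexible_residue_localized(self):
        ensemble, site, mappings = self._ensemble([{}, {5: (1.5, 0, 0)}, {}])
        _, _, maxima = per_residue_rmsd_stats(ensemble, site, mappings)
        assert maxima[("A", 5, "")] == pytest.approx(1.5, abs=1e-12)
        assert all(v == 0.0 for k, v in maxima.items() if k != ("A", 5, ""))

    def test_matrix_matches_brute_force(self):
        displacements = [{}, {2: (1.0, 0, 0)}, {2: (0, 2.0, 0), 6: (1.0, 1.0, 0)}]
        ensemble, site, mappings = self._ensemble(displacements)
        matrix, means, _ = per_residue_rmsd_stats(ensemble, site, mappings)
        assert np.allclose(matrix, matrix.T)
        assert np.all(np.diag(matrix) == 0.0)
        # independent double loop over paired site backbone atoms
        n = len(ensemble.members)
        for i in range(n):
            for j in range(n):
                a = ensemble.members[i]
                b = ensemble.members[j]
                deltas = []
                for atom_a, atom_b in zip(a.atoms, b.atoms):
                    if atom_a.name in ("N", "CA", "C", "O"):
                        deltas.append(np.sum((atom_a.coords - atom_b.coords) ** 2))
                expected = np.sqrt(np.mean(deltas))
                assert matrix[i, j] == pytest.approx(expected, abs=1e-12)
        # per-member mean: residue-wise RMSD vs reference, then averaged
        for m, disp in enumerate(displacements):
            per_res = []
            for seq in range(1, len(NAMES) + 1):
                shift = np.asarray(disp.get(seq, (0.0, 0.0, 0.0)))
                per_res.append(np.linalg.norm(shift))
            assert means[m] == pytest.approx(np.mean(per_res), abs=1e-12)
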