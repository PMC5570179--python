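import numpy as np
import pytest
from helpers import brute_force_pocket, make_residue

from pocketdyn.binding_site import BindingSiteDefinition, define_site_from_point
from pocketdyn.fixtures import ToyEnsembleSpec, make_shell_structure, make_toy_ensemble
from pocketdyn.io_formats import Structure
from pocketdyn.pocket_grid import (build_grid, detect_pocket, _protein_mask,
                                   lining_residue_comparison, pocket_stats,
                                   DEFAULT_PROBE_RADIUS)


class TestBuildGrid:
    def test_dims_cover_site_plus_margin(self, shell):
        any_key = shell.residues[:1]
        site = BindingSiteDefinition(center=np.zeros(3), radius=5.0,
                                     residue_keys=any_key, source="point")
        grid = build_grid(site, margin=2.0, spacing=1.0)
        assert grid.dims == (15, 15, 15)  # 2*ceil((5+2)/1)+1, center-snapped
        center_idx = (np.asarray(site.center) - grid.origin) / grid.spacing
        assert np.allclose(center_idx, np.round(center_idx))

    def test_spacing_bounds(self, shell_site):
        with pytest.raises(ValueError):
            build_grid(shell_site, spacing=0.1)
        with pytest.raises(ValueError):
            build_grid(shell_site, spacing=3.0)

    def test_deterministic(self, shell_site):
        a = build_grid(shell_site, margin=2.0, spacing=1.0)
        b = build_grid(shell_site, margin=2.0, spacing=1.0)
        assert a.same_geometry(b)


class TestDetectPocket:
    def test_no_heavy_atoms_errors(self, shell_site):
        grid = build_grid(shell_site, spacing=1.0)
        with pytest.raises(ValueError):
            detect_pocket(Structure(id="empty"), grid, shell_site)

    def test_matches_brute_force_oracle(self, shell, shell_site):
        grid = build_grid(shell_site, margin=2.0, spacing=1.0)
        pocket = detect_pocket(shell, grid, shell_site)
        oracle = brute_force_pocket(shell, grid, shell_site.center, shell_site.radius)
        assert np.array_equal(pocket.grid.values, oracle)
        assert pocket.n_points > 0

    def test_open_wall_shrinks_pocket(self, shell, shell_site):
        spec = ToyEnsembleSpec(hollow_radius=5.0, subpocket_open_fraction=1.0,
                               n_members=1)
        opened = make_toy_ensemble(spec).open_exemplar()
        grid = build_grid(shell_site, margin=2.0, spacing=1.0)
        closed_pocket = detect_pocket(shell, grid, shell_site).grid.values
        open_pocket = detect_pocket(opened, grid, shell_site).grid.values
        # the planted opening only adds cavity beyond the closed wall
        assert open_pocket.sum() > closed_pocket.sum()
        inner = closed_pocket & open_pocket
        assert inner.sum() >= 0.95 * closed_pocket.sum()

    def test_pocket_disjoint_from_protein(self, shell, shell_site):
        grid = build_grid(shell_site, margin=2.0, spacing=1.0)
        pocket = detect_pocket(shell, grid, shell_site)
        protein = _protein_mask(shell, grid, DEFAULT_PROBE_RADIUS)
        assert not np.any(pocket.grid.values & protein)

    def test_translation_invariance_by_integer_spacings(self, shell, shell_site):
        grid = build_grid(shell_site, margin=2.0, spacing=1.0)
        pocket = detect_pocket(shell, grid, shell_site)
        shift = np.array([3.0, -2.0, 5.0])  # integer multiples of spacing
        moved = shell.transformed(np.eye(3), shift)
        moved_site = BindingSiteDefinition(
            center=shell_site.center + shift, radius=shell_site.radius,
            residue_keys=shell_site.residue_keys, source=shell_site.source)
        moved_grid = grid.like(grid.values)
        moved_grid.origin = grid.origin + shift
        moved_pocket = detect_pocket(moved, moved_grid, moved_site)
        assert np.array_equal(pocket.grid.values, moved_pocket.grid.values)


def _asp_sidechain(base):
    # side chain extending from ``base`` toward -z (into the cavity)
    b = np.asarray(base, dtype=float)
    return [("CB", "C", tuple(b + [0.0, 0.0, -0.6])),
            ("CG", "C", tuple(b + [0.0, 0.0, -1.2])),
            ("OD1", "O", tuple(b + [0.6, 0.0, -1.8])),
            ("OD2", "O", tuple(b + [-0.6, 0.0, -1.8]))]


class TestPocketStats:
    def test_empty_pocket(self, shell, shell_site):
        grid = build_grid(shell_site, spacing=1.0)
        from pocketdyn.pocket_grid import PocketGrid
        empty = PocketGrid(grid=grid.like(np.zeros(grid.dims, dtype=bool)),
                           structure_id="empty")
        stats = pocket_stats(empty, shell)
        assert stats.volume == 0.0
        assert stats.surface_area == 0.0
        assert not stats.lining_residues

    def test_volume_is_point_count_times_spacing_cubed(self, shell, shell_site):
        grid = build_grid(shell_site, spacing=1.0)
        pocket = detect_pocket(shell, grid, shell_site)
        stats = pocket_stats(pocket, shell)
        assert stats.volume == pocket.n_points * 1.0 ** 3
        half = build_grid(shell_site, spacing=0.5)
        pocket_half = detect_pocket(shell, half, shell_site)
        stats_half = pocket_stats(pocket_half, shell)
        assert stats_half.volume == pocket_half.n_points * 0.5 ** 3

    def test_asp_at_wall_types_negative_acceptor(self, shell, shell_site):
        modified = shell.copy()
        # an Asp side chain pointing into the cavity from the inner wall
        wall_point = np.array([0.0, 0.0, 7.9])
        serial = len(modified.atoms) + 1
        modified.atoms.extend(
            make_residue("A", 9999, "ASP", _asp_sidechain(wall_point),
                         serial_start=serial))
        grid = build_grid(shell_site, spacing=1.0)
        pocket = detect_pocket(modified, grid, shell_site)
        stats = pocket_stats(pocket, modified, contact_distance=4.0)
        assert ("A", 9999, "") in stats.lining_residues
        assert stats.property_counts["negative"] > 0
        assert stats.property_counts["acceptor"] > 0
        # oracle: distance scan of the typing table against pocket points
        pocket_pts = grid.point_coords().reshape(*grid.dims, 3)[pocket.grid.values]
        od = [a.coords for a in modified.atoms if a.name in ("OD1", "OD2")]
        n_neg = sum(
            1 for p in pocket_pts
            if any(np.linalg.norm(p - o) <= 4.0 for o in od)
        )
        assert stats.property_counts["negative"] == n_neg

    def test_enclosed_cavity_has_no_solvent_faces(self, shell, shell_site):
        grid = build_grid(shell_site, spacing=1.0)
        pocket = detect_pocket(shell, grid, shell_site)
        stats = pocket_stats(pocket, shell)
        # every boundary face of a sealed cavity abuts protein, not solvent
        assert stats.surface_area == 0.0

    def test_surface_counts_solvent_faces_exactly(self, shell, shell_site):
        from pocketdyn.pocket_grid import PocketGrid
        # a free-standing 2x2x2 pocket block far from any atom: all 24 outer
        # faces are solvent-exposed
        grid = build_grid(shell_site, spacing=1.0)
        mask = np.zeros(grid.dims, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        far = Structure(id="far")
        from helpers import make_residue
        far.atoms.extend(make_residue("A", 1, "ALA", [("CA", "C", (500.0, 0, 0))]))
        stats = pocket_stats(PocketGrid(grid=grid.like(mask), structure_id="s"), far)
        assert stats.surface_area == 24.0
        # at spacing 0.5 the same block has faces of area 0.25
        half = build_grid(shell_site, spacing=0.5)
        mask2 = np.zeros(half.dims, dtype=bool)
        mask2[1:3, 1:3, 1:3] = True
        stats2 = pocket_stats(PocketGrid(grid=half.like(mask2), structure_id="s"), far)
        assert stats2.surface_area == 24 * 0.25


class TestLiningComparison:
    def _stats(self, idents, struct_id="s"):
        from pocketdyn.pocket_grid import PocketStats
        from pocketdyn.io_formats import ResidueKey
        keys = [ResidueKey("A", i, "", "ALA") for i in idents]
        return PocketStats(structure_id=struct_id, volume=0, surface_area=0,
                           lining_residues={k.ident for k in keys},
                           lining_residue_keys=keys, property_counts={})

    def test_identical_members_all_shared(self):
        ref = self._stats([1, 2, 3])
        table = lining_residue_comparison([ref, ref, ref], ref)
        assert set(table["status"]) == {"shared"}
        assert set(table["fraction_lining"]) == {1.0}

    def test_reference_only_residue_flagged_lost(self):
        table = lining_residue_comparison([self._stats([1])], self._stats([1, 2]))
        row = table[table["res_seq"] == 2].iloc[0]
        assert row["status"] == "lost"
        assert row["fraction_lining"] == 0.0

    def test_fraction_counts_members(self):
        members = [self._stats([1, 7]), self._stats([1, 7]), self._stats([1, 7]),
                   self._stats([1]), self._stats([1])]
        table = lining_residue_comparison(members, self._stats([1]))
        row = table[table["res_seq"] == 7].iloc[0]
        assert row["fraction_lining"] == pytest.approx(0.6)
        assert row["status"] == "new"
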