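"""Atlas mapping: sphere geometry, overlap counting, filtering, assignment."""

import numpy as np
import pandas as pd
import pytest

from ernconn.netdef_atlas import (
    AtlasError,
    LabelVolume,
    NetworkDefinition,
    ParcelOverlapTable,
    assign_parcels,
    compute_overlap,
    default_network_definition,
    filter_overlap,
    load_network_definition,
    sphere_voxels,
)

from conftest import brute_force_overlap, overlap_as_dict


class TestLoadDefinition:
    def test_toy_file_parses_identically(self, tmp_path, toy_definition):
        p = tmp_path / "nets.tsv"
        toy_definition.table.to_csv(p, sep="\t", index=False)
        loaded = load_network_definition(p)
        assert len(loaded) == 4
        pd.testing.assert_frame_equal(loaded.table, toy_definition.table)

    def test_packaged_definition_has_36_rois(self):
        nets = default_network_definition()
        assert len(nets) == 36
        assert nets.networks == ["ERN1", "ERN2", "ERN3", "ERN4"]

    def test_unknown_network_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("network\tlabel\tx\ty\tz\nERN5\tq\t0\t0\t0\n")
        with pytest.raises(AtlasError, match="ERN5"):
            load_network_definition(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("network\tlabel\tx\ty\nERN1\tq\t0\t0\n")
        with pytest.raises(AtlasError, match="missing"):
            load_network_definition(p)

    def test_nonnumeric_coordinate_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("network\tlabel\tx\ty\tz\nERN1\tq\tfoo\t0\t0\n")
        with pytest.raises((ValueError, AtlasError)):
            load_network_definition(p)


class TestSphereVoxels:
    def test_radius_zero_hits_single_voxel(self, toy_volume):
        assert sphere_voxels(np.array([2.0, 3.0, 4.0]), 0.0, toy_volume) == {(2, 3, 4)}

    def test_lattice_count_on_1mm_grid(self):
        # brute-force integer-lattice oracle: points with x^2+y^2+z^2 <= 36
        r = np.arange(-6, 7)
        xx, yy, zz = np.meshgrid(r, r, r, indexing="ij")
        expected = int((xx**2 + yy**2 + zz**2 <= 36).sum())
        grid = np.ones((21, 21, 21), dtype=np.int32)
        vol = LabelVolume(grid=grid, affine=np.eye(4))
        vox = sphere_voxels(np.array([10.0, 10.0, 10.0]), 6.0, vol)
        assert len(vox) == expected

    def test_2mm_grid_matches_per_voxel_oracle(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        vol = LabelVolume(grid=np.ones((11, 11, 11), dtype=np.int32), affine=aff)
        center = np.array([10.0, 10.0, 10.0])  # mm, voxel (5,5,5)
        got = sphere_voxels(center, 6.0, vol)
        expected = set()
        for i in range(11):
            for j in range(11):
                for k in range(11):
                    mm = vol.voxel_to_mm(np.array([i, j, k]))[0]
                    if np.sum((mm - center) ** 2) <= 36.0 + 1e-9:
                        expected.add((i, j, k))
        assert got == expected

    @pytest.mark.parametrize("r_small,r_big", [(0.0, 2.0), (2.0, 4.5), (4.5, 8.0)])
    def test_monotone_in_radius(self, toy_volume, r_small, r_big):
        c = np.array([2.5, 2.5, 2.5])
        assert sphere_voxels(c, r_small, toy_volume) <= sphere_voxels(c, r_big, toy_volume)

    def test_far_outside_center_is_empty_with_warning(self, toy_volume):
        with pytest.warns(UserWarning, match="outside"):
            out = sphere_voxels(np.array([100.0, 100.0, 100.0]), 2.0, toy_volume)
        assert out == set()

    def test_negative_radius_rejected(self, toy_volume):
        with pytest.raises(AtlasError):
            sphere_voxels(np.zeros(3), -1.0, toy_volume)


class TestComputeOverlap:
    def test_single_parcel_volume_collects_all_roi_voxels(self, toy_definition):
        vol = LabelVolume(grid=np.ones((6, 6, 6), dtype=np.int32), affine=np.eye(4))
        table = compute_overlap(toy_definition, vol, mode="peak", radius_mm=1.0)
        got = overlap_as_dict(table)
        for r in toy_definition.table.itertuples():
            n = len(sphere_voxels(np.array([r.x, r.y, r.z]), 1.0, vol))
            assert got[(r.network, 1)] == n

    def test_straddling_sphere_counts_sum_to_sphere_size(self, toy_volume):
        nets = NetworkDefinition(table=pd.DataFrame([
            {"network": "ERN1", "label": "mid", "x": 2.5, "y": 2.5, "z": 2.5}
        ]))
        table = compute_overlap(nets, toy_volume, mode="peak", radius_mm=2.0)
        got = overlap_as_dict(table)
        n_sphere = len(sphere_voxels(np.array([2.5, 2.5, 2.5]), 2.0, toy_volume))
        assert got[("ERN1", 1)] + got[("ERN1", 2)] == n_sphere

    def test_background_peak_warns_and_emits_nothing(self):
        grid = np.zeros((6, 6, 6), dtype=np.int32)
        grid[0, 0, 0] = 1
        vol = LabelVolume(grid=grid, affine=np.eye(4))
        nets = NetworkDefinition(table=pd.DataFrame([
            {"network": "ERN2", "label": "bg", "x": 4.0, "y": 4.0, "z": 4.0}
        ]))
        with pytest.warns(UserWarning, match="background"):
            table = compute_overlap(nets, vol, mode="peak", radius_mm=1.0)
        assert len(table.table) == 0

    def test_matches_exhaustive_loop_on_random_volumes(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            shape = tuple(rng.integers(5, 13, size=3))
            n_parcels = int(rng.integers(1, 5))
            grid = rng.integers(0, n_parcels + 1, size=shape).astype(np.int32)
            aff = np.diag([*rng.uniform(1, 3, size=3), 1.0])
            aff[:3, 3] = rng.uniform(-5, 5, size=3)
            vol = LabelVolume(grid=grid, affine=aff)
            rows = []
            for i in range(int(rng.integers(1, 4))):
                net = f"ERN{rng.integers(1, 5)}"
                mm = vol.voxel_to_mm(rng.uniform(0, np.array(shape) - 1))[0]
                rows.append({"network": net, "label": f"p{i}", "x": mm[0], "y": mm[1], "z": mm[2]})
            nets = NetworkDefinition(table=pd.DataFrame(rows))
            radius = float(rng.uniform(0, 6))
            table = compute_overlap(nets, vol, mode="peak", radius_mm=radius)
            assert overlap_as_dict(table) == brute_force_overlap(nets, vol, radius)

    def test_affine_translation_invariance(self, toy_definition):
        rng = np.random.default_rng(7)
        grid = rng.integers(1, 4, size=(8, 8, 8)).astype(np.int32)
        aff = np.eye(4)
        vol = LabelVolume(grid=grid, affine=aff)
        t1 = compute_overlap(toy_definition, vol, radius_mm=2.5)
        shift = np.array([10.0, -4.0, 3.0])
        aff2 = aff.copy()
        aff2[:3, 3] += shift
        moved = toy_definition.table.copy()
        moved[["x", "y", "z"]] += shift
        t2 = compute_overlap(
            NetworkDefinition(table=moved), LabelVolume(grid=grid, affine=aff2), radius_mm=2.5
        )
        assert overlap_as_dict(t1) == overlap_as_dict(t2)


def _table(rows):
    return ParcelOverlapTable(table=pd.DataFrame(
        rows, columns=["network_id", "parcel_id", "voxel_count"]))


class TestFilterOverlap:
    def test_quartile_rule_hand_computed(self):
        # pooled counts {2, 5, 8, 11}: Q1 (linear interpolation) = 4.25,
        # so only the count-2 row is dropped
        t = _table([("ERN1", 1, 2), ("ERN1", 2, 5), ("ERN2", 3, 8), ("ERN2", 4, 11)])
        with pytest.raises(AtlasError, match="ERN1"):
            # dropping parcel 1 leaves ERN1 with one parcel -> named error
            filter_overlap(t, rule="quartile")
        # pooled counts {2, 3, 8, 9, 10, 11}: Q1 = 3 + 0.25*(8-3) = 4.25,
        # dropping the 2- and 3-voxel rows; both networks keep 2 parcels
        t2 = _table([("ERN1", 1, 3), ("ERN1", 2, 9), ("ERN1", 5, 10),
                     ("ERN2", 3, 8), ("ERN2", 4, 11), ("ERN2", 6, 2)])
        out = filter_overlap(t2, rule="quartile")
        assert set(out.table["voxel_count"]) == {8, 9, 10, 11}

    def test_fixed_rule_drops_at_most_five_voxels(self):
        t = _table([("ERN1", 1, 2), ("ERN1", 2, 5), ("ERN1", 5, 6),
                    ("ERN1", 6, 7), ("ERN2", 3, 8), ("ERN2", 4, 11)])
        out = filter_overlap(t, rule="fixed", fixed_min=5)
        assert set(out.table["voxel_count"]) == {6, 7, 8, 11}

    def test_all_equal_counts_is_degenerate(self):
        t = _table([("ERN1", 1, 4), ("ERN1", 2, 4), ("ERN2", 3, 4), ("ERN2", 4, 4)])
        with pytest.raises(AtlasError):
            filter_overlap(t, rule="quartile")

    def test_empty_table_rejected(self):
        with pytest.raises(AtlasError):
            filter_overlap(_table([]), rule="fixed")


class TestAssignParcels:
    def test_largest_overlap_wins(self):
        t = _table([("ERN1", 7, 10), ("ERN3", 7, 3),
                    ("ERN1", 8, 4), ("ERN3", 9, 5), ("ERN3", 10, 6)])
        m = assign_parcels(t)
        assert m.assignment[7] == "ERN1"

    def test_tie_broken_to_lowest_index_with_warning(self):
        t = _table([("ERN2", 7, 5), ("ERN4", 7, 5),
                    ("ERN2", 8, 4), ("ERN4", 9, 5), ("ERN4", 10, 2)])
        with pytest.warns(UserWarning, match="tie"):
            m = assign_parcels(t)
        assert m.assignment[7] == "ERN2"

    def test_disjoint_overlaps_identity(self):
        rows = [("ERN1", 1, 5), ("ERN1", 2, 6), ("ERN2", 3, 7), ("ERN2", 4, 8)]
        m = assign_parcels(_table(rows))
        assert m.assignment == {1: "ERN1", 2: "ERN1", 3: "ERN2", 4: "ERN2"}

    def test_row_order_invariance_and_functionality(self):
        rows = [("ERN1", 1, 5), ("ERN2", 1, 3), ("ERN1", 2, 2), ("ERN1", 5, 9),
                ("ERN2", 3, 7), ("ERN2", 4, 8)]
        m1 = assign_parcels(_table(rows))
        m2 = assign_parcels(_table(rows[::-1]))
        assert m1.assignment == m2.assignment
        # each parcel under exactly one network
        assert len(m1.assignment) == len({*m1.assignment})

    def test_assignment_below_two_parcels_errors(self):
        t = _table([("ERN1", 1, 9), ("ERN2", 1, 3), ("ERN2", 2, 5), ("ERN1", 4, 2)])
        with pytest.raises(AtlasError):
            assign_parcels(t)


class TestClusterMode:
    def test_cluster_mask_resampled_and_counted(self, tmp_path, toy_volume):
        import nibabel as nib
        mask = np.zeros((6, 6, 6), dtype=np.int16)
        mask[1:3, 1:3, 1:3] = 1  # 8-voxel cube entirely inside parcel 1
        nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "m.nii.gz")
        t = pd.DataFrame([{"network": "ERN1", "label": "c", "x": 0.0, "y": 0.0,
                           "z": 0.0, "mask_path": str(tmp_path / "m.nii.gz")}])
        table = compute_overlap(NetworkDefinition(table=t), toy_volume, mode="cluster")
        got = {(r.network_id, r.parcel_id): r.voxel_count for r in table.table.itertuples()}
        assert got == {("ERN1", 1): 8}

    def test_cluster_mode_without_mask_rejected(self, toy_definition, toy_volume):
        with pytest.raises(AtlasError, match="mask_path"):
            compute_overlap(toy_definition, toy_volume, mode="cluster")
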