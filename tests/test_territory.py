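import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renoterra import (
    ConsistencyError,
    Fiducial,
    FiducialSet,
    ImageGrid,
    ParenchymaMask,
    ValidationError,
    aggregate_by_artery,
    assign_territories,
    brute_force_assign,
    generate_phantom,
    territory_volumes,
)
from conftest import random_spec


def ep(i, name, pos, artery="A1"):
    return Fiducial(id=i, name=name, role="endpoint", artery=artery, position=np.array(pos, float))


def row_mask(n, spacing=(1.0, 1.0, 1.0)):
    grid = ImageGrid(dims=(n, 1, 1), spacing=spacing)
    return ParenchymaMask(grid=grid, occupancy=np.ones((n, 1, 1), bool))


class TestAssignment:
    def test_single_endpoint_takes_everything(self, bundle):
        fids = [ep(0, "endpoint:A1:e1", [5.0, 5.0, 5.0])]
        tmap = assign_territories(bundle.mask, fids)
        fg = bundle.mask.occupancy
        assert np.array_equal(tmap.labels[fg], np.ones(fg.sum(), dtype=np.int32))
        assert (tmap.labels[~fg] == 0).all()

    def test_two_endpoints_split_a_row(self):
        mask = row_mask(4)
        fids = [ep(0, "e0", [0, 0, 0]), ep(1, "e1", [3, 0, 0], artery="A2")]
        tmap = assign_territories(mask, fids)
        assert tmap.labels[:, 0, 0].tolist() == [1, 1, 2, 2]

    def test_midpoint_tie_goes_to_smallest_id(self):
        mask = row_mask(3)
        fids = [ep(0, "e0", [0, 0, 0]), ep(1, "e1", [2, 0, 0], artery="A2")]
        tmap = assign_territories(mask, fids)
        assert tmap.labels[:, 0, 0].tolist() == [1, 1, 2]
        # same layout, reversed file order: the tied voxel follows the new id 0
        rev = [ep(0, "e1", [2, 0, 0], artery="A2"), ep(1, "e0", [0, 0, 0])]
        tmap2 = assign_territories(mask, rev)
        assert tmap2.labels[:, 0, 0].tolist() == [2, 1, 1]

    def test_zero_endpoints_rejected(self, bundle):
        with pytest.raises(ValidationError):
            assign_territories(bundle.mask, [])
        with pytest.raises(ValidationError):
            brute_force_assign(bundle.mask, [])

    def test_coincident_endpoints_rejected(self, bundle):
        fids = [ep(0, "e0", [5, 5, 5]), ep(1, "e1", [5, 5, 5 + 1e-8], artery="A2")]
        with pytest.raises(ValidationError):
            assign_territories(bundle.mask, fids)

    def test_endpoint_outside_mask_warns(self, bundle):
        fids = [ep(0, "e0", [-50.0, -50.0, -50.0])]
        with pytest.warns(UserWarning, match="outside the parenchyma"):
            assign_territories(bundle.mask, fids)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_kdtree_matches_bruteforce_and_conserves(self, seed):
        """assign_territories must equal the exhaustive oracle voxel-wise, and
        every foreground voxel must be assigned, on random anisotropic phantoms."""
        b = generate_phantom(random_spec(seed))
        fast = assign_territories(b.mask, b.fiducials)
        slow = brute_force_assign(b.mask, b.fiducials)
        assert np.array_equal(fast.labels, slow.labels)
        assert fast.foreground_count == b.mask.foreground_count

    def test_anisotropic_distances_use_world_mm(self):
        # spacing (1,1,4): in index space voxel (0,0,1) is as close to an
        # endpoint at (0,0,0) as voxel (0,3,0); in world mm it is not.
        grid = ImageGrid(dims=(1, 5, 3), spacing=(1.0, 1.0, 4.0))
        mask = ParenchymaMask(grid=grid, occupancy=np.ones((1, 5, 3), bool))
        fids = [ep(0, "e0", [0, 0, 0]), ep(1, "e1", [0, 4, 8], artery="A2")]
        tmap = assign_territories(mask, fids)
        assert tmap.labels[0, 3, 0] == 1  # 3 mm from e0, >8 mm from e1
        assert tmap.labels[0, 0, 2] == 2  # 8 mm from e0, ~4 mm... belongs to e1

    def test_rigid_transform_leaves_counts_unchanged(self, bundle):
        theta = 0.37
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shift = np.array([12.0, -7.0, 3.0])
        g = bundle.mask.grid
        g2 = ImageGrid(
            dims=g.dims,
            spacing=g.spacing,
            origin=tuple(R @ np.asarray(g.origin) + shift),
            direction=tuple((R @ g.direction_matrix).ravel()),
        )
        mask2 = ParenchymaMask(grid=g2, occupancy=bundle.mask.occupancy)
        fset2 = FiducialSet(
            fiducials=[
                Fiducial(id=f.id, name=f.name, role=f.role, artery=f.artery,
                         position=R @ f.position + shift)
                for f in bundle.fiducials.fiducials
            ]
        )
        t1 = territory_volumes(assign_territories(bundle.mask, bundle.fiducials), bundle.fiducials)
        t2 = territory_volumes(assign_territories(mask2, fset2), fset2)
        assert t1.endpoints["voxel_count"].tolist() == t2.endpoints["voxel_count"].tolist()

    def test_endpoint_order_invariance_by_name(self, bundle):
        eps = bundle.fiducials.endpoints
        perm = np.random.default_rng(5).permutation(len(eps))
        shuffled = [
            Fiducial(id=i, name=eps[j].name, role="endpoint", artery=eps[j].artery,
                     position=eps[j].position.copy())
            for i, j in enumerate(perm)
        ]
        t1 = territory_volumes(assign_territories(bundle.mask, eps), eps)
        t2 = territory_volumes(assign_territories(bundle.mask, shuffled), shuffled)
        v1 = dict(zip(t1.endpoints["name"], t1.endpoints["voxel_count"]))
        v2 = dict(zip(t2.endpoints["name"], t2.endpoints["voxel_count"]))
        assert v1 == v2

    def test_adding_endpoint_never_grows_existing_territories(self, bundle):
        eps = bundle.fiducials.endpoints
        t1 = territory_volumes(assign_territories(bundle.mask, eps), eps)
        extra = eps + [
            Fiducial(id=len(eps), name="endpoint:A1:extra", role="endpoint", artery="A1",
                     position=np.array([20.0, 20.0, 15.0]))
        ]
        extra = [
            Fiducial(id=i, name=f.name, role=f.role, artery=f.artery, position=f.position)
            for i, f in enumerate(extra)
        ]
        t2 = territory_volumes(assign_territories(bundle.mask, extra), extra)
        v1 = dict(zip(t1.endpoints["name"], t1.endpoints["voxel_count"]))
        v2 = dict(zip(t2.endpoints["name"], t2.endpoints["voxel_count"]))
        assert all(v2[n] <= v1[n] for n in v1)


class TestVolumes:
    def test_thousand_unit_voxels_is_one_cm3(self):
        mask = row_mask(1000)
        fids = [ep(0, "e0", [0, 0, 0])]
        table = territory_volumes(assign_territories(mask, fids), fids)
        assert table.endpoints["volume_cm3"].iloc[0] == pytest.approx(1.0)
        assert table.total_volume_cm3 == pytest.approx(1.0)

    def test_mirror_symmetric_endpoints_get_equal_volumes(self):
        grid = ImageGrid(dims=(10, 5, 5), spacing=(1, 1, 1))
        mask = ParenchymaMask(grid=grid, occupancy=np.ones((10, 5, 5), bool))
        # reflected about x = 4.5 mm; no voxel centre is equidistant
        fids = [ep(0, "e0", [2.0, 2.0, 2.0]), ep(1, "e1", [7.0, 2.0, 2.0], artery="A2")]
        table = territory_volumes(assign_territories(mask, fids), fids)
        assert table.endpoints["voxel_count"].iloc[0] == table.endpoints["voxel_count"].iloc[1]

    def test_zero_voxel_endpoints_reported_not_dropped(self):
        mask = row_mask(3)
        # e2 is crowded out: every voxel is nearer e0 or e1
        fids = [ep(0, "e0", [0, 0, 0]), ep(1, "e1", [2, 0, 0], artery="A2"),
                ep(2, "e2", [100, 0, 0], artery="A3")]
        table = territory_volumes(assign_territories(mask, fids), fids)
        assert table.endpoints["voxel_count"].tolist() == [2, 1, 0]
        assert table.endpoints["volume_cm3"].iloc[2] == 0.0

    def test_orphan_label_is_consistency_error(self, bundle):
        eps = bundle.fiducials.endpoints
        with pytest.raises(ConsistencyError):
            territory_volumes(bundle.truth_map, eps[:1])

    def test_planted_truth_table_recovered_exactly(self, bundle):
        tmap = assign_territories(bundle.mask, bundle.fiducials)
        table = territory_volumes(tmap, bundle.fiducials)
        assert table.endpoints["voxel_count"].tolist() == (
            bundle.truth_table.endpoints["voxel_count"].tolist()
        )
        assert table.total_volume_cm3 == bundle.truth_table.total_volume_cm3

    def test_fractions_sum_to_one(self, bundle):
        assert bundle.truth_table.endpoints["fraction"].sum() == pytest.approx(1.0, abs=1e-9)


class TestArteryAggregation:
    def test_additivity(self, bundle):
        table = bundle.truth_table
        for _, row in table.arteries.iterrows():
            eps = table.endpoints[table.endpoints["artery"] == row["artery"]]
            assert row["volume_cm3"] == pytest.approx(eps["volume_cm3"].sum(), rel=0, abs=0)
        assert table.arteries["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_artery_has_fraction_one(self):
        mask = row_mask(10)
        fids = [ep(0, "e0", [0, 0, 0]), ep(1, "e1", [9, 0, 0])]
        table = aggregate_by_artery(territory_volumes(assign_territories(mask, fids), fids), fids)
        assert len(table.arteries) == 1
        assert table.arteries["fraction"].iloc[0] == pytest.approx(1.0)

    def test_artery_sums_match_labelmap_recount(self, bundle):
        labels = bundle.truth_map.labels
        for _, row in bundle.truth_table.arteries.iterrows():
            ids = [f.id + 1 for f in bundle.fiducials.endpoints if f.artery == row["artery"]]
            recount = int(np.isin(labels, ids).sum())
            assert recount == int(row["voxel_count"])
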