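"""Cluster skimming, component labeling, intensity and weak-edge filters."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import infarctseg as iseg
from infarctseg.fcm import FCMResult
from infarctseg.screening import (
    EdgeMap,
    LesionLabel,
    canny_edge_map,
    filter_labels_by_edge,
    filter_labels_by_intensity,
    label_components,
    skim_clusters,
)

from conftest import make_volume


def fake_fcm(cluster_means):
    k = len(cluster_means)
    return FCMResult(
        centers=np.asarray(cluster_means, float),
        memberships=np.eye(k),
        hard_assignment=np.arange(k),
        cluster_means=np.asarray(cluster_means, float),
        objective_trace=np.array([0.0]),
    )


class TestSkim:
    def test_strictly_greater_than_peak_plus_offset(self):
        res = fake_fcm([0.3, 0.55, 0.8])
        assert list(skim_clusters(res, peak=0.4, offset=0.2)) == [2]

    def test_zero_offset_selects_all_above_peak(self):
        res = fake_fcm([0.3, 0.55, 0.8])
        assert list(skim_clusters(res, peak=0.4, offset=0.0)) == [1, 2]

    def test_no_cluster_above_threshold(self):
        res = fake_fcm([0.1, 0.2])
        assert len(skim_clusters(res, peak=0.4, offset=0.2)) == 0


class TestLabelComponents:
    def _dwi(self, shape=(6, 6, 4)):
        return make_volume(np.full(shape, 0.5))

    def test_diagonal_voxels_are_one_label_under_26_connectivity(self):
        voxels = np.array([[1, 1, 1], [2, 2, 2]])
        labels = label_components(voxels, self._dwi(), connectivity="3d26")
        assert len(labels) == 1
        assert labels[0].size == 2

    def test_per_slice_connectivity_splits_across_slices(self):
        voxels = np.array([[1, 1, 1], [1, 1, 2]])
        labels = label_components(voxels, self._dwi(), connectivity="8-per-slice")
        assert len(labels) == 2

    def test_isolated_voxels_give_one_label_each(self):
        voxels = np.array([[0, 0, 0], [0, 0, 2], [3, 3, 0], [5, 5, 3]])
        labels = label_components(voxels, self._dwi(), connectivity="3d26")
        assert len(labels) == 4  # label count bounded by voxel count

    def test_empty_input(self):
        assert label_components(np.empty((0, 3), int), self._dwi()) == []

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(size=(8, 8, 4)) > 0.6
        voxels = np.argwhere(grid)
        labels = label_components(voxels, self._dwi((8, 8, 4)))
        all_voxels = np.concatenate([l.voxels for l in labels])
        assert len(all_voxels) == len(voxels)  # union = input
        assert len({tuple(v) for v in all_voxels}) == len(all_voxels)  # disjoint

    def test_majority_source_cluster_recorded(self):
        voxels = np.array([[1, 1, 1], [1, 2, 1], [1, 3, 1]])
        labels = label_components(
            voxels, self._dwi(), cluster_of_voxel=np.array([4, 4, 9])
        )
        assert len(labels) == 1
        assert labels[0].source_cluster == 4


class TestIntensityFilter:
    def _label(self, mean):
        return LesionLabel(label_id=1, voxels=np.array([[0, 0, 0]]), mean_dwi=mean)

    def test_mean_exactly_at_threshold_eliminated(self):
        retained, eliminated = filter_labels_by_intensity(
            [self._label(0.6)], peak=0.4, offset=0.2
        )
        assert not retained and eliminated[0].verdict == "low_intensity"

    def test_mean_just_above_threshold_retained(self):
        retained, eliminated = filter_labels_by_intensity(
            [self._label(0.61)], peak=0.4, offset=0.2
        )
        assert retained and not eliminated

    def test_bright_label_with_faint_suburb_retained_whole(self):
        """a label is judged by its whole-label mean: a bright core with a
        faint suburb stays intact when the mean clears the threshold."""
        voxels = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0]])
        lab = LesionLabel(label_id=1, voxels=voxels, mean_dwi=np.mean([0.9, 0.9, 0.3]))
        retained, _ = filter_labels_by_intensity([lab], peak=0.4, offset=0.2)
        assert retained and retained[0].size == 3


def disk_slice(shape=(48, 48), center=(24, 24), radius=9, height=0.6, base=0.2):
    x, y = np.ogrid[: shape[0], : shape[1]]
    img = np.full(shape, base)
    img[(x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2] = base + height
    return img


class TestCanny:
    def test_sharp_disk_yields_ring_near_boundary(self):
        img = disk_slice()
        vol = make_volume(img[:, :, None])
        edges = canny_edge_map(vol).data[:, :, 0]
        assert edges.any()
        x, y = np.ogrid[:48, :48]
        r = np.sqrt((x - 24.0) ** 2 + (y - 24.0) ** 2)
        ring_zone = (r > 6) & (r < 12)
        assert edges[ring_zone].sum() >= 0.9 * edges.sum()  # edges hug the boundary

    def test_constant_slice_has_no_edges(self):
        vol = make_volume(np.full((32, 32, 1), 0.4))
        assert not canny_edge_map(vol).data.any()

    def test_blurred_disk_loses_its_ring(self):
        """with a sharp reference edge in the slice, a sigma-4-blurred disk's
        gradient falls below the 0.3 relative threshold and produces no ring."""
        img = disk_slice(center=(12, 24), radius=7)
        soft = ndi.gaussian_filter(disk_slice(center=(34, 24), radius=7), 4.0)
        combined = np.maximum(img, soft)
        edges = canny_edge_map(make_volume(combined[:, :, None])).data[:, :, 0]
        x, y = np.ogrid[:48, :48]
        near_soft = np.sqrt((x - 34.0) ** 2 + (y - 24.0) ** 2) < 12
        near_sharp = np.sqrt((x - 12.0) ** 2 + (y - 24.0) ** 2) < 11
        assert edges[near_sharp].sum() > 10
        assert edges[near_soft & ~near_sharp].sum() == 0


class TestEdgeFilter:
    def _square_label(self, x0=10, x1=20, y0=10, y1=20, z=0):
        coords = [[x, y, z] for x in range(x0, x1) for y in range(y0, y1)]
        return LesionLabel(label_id=1, voxels=np.array(coords), mean_dwi=0.8)

    def test_boundary_on_canny_ring_fully_supported(self):
        img = np.full((32, 32, 1), 0.2)
        img[10:20, 10:20, 0] = 0.8
        edges = canny_edge_map(make_volume(img))
        lab = self._square_label()
        retained, eliminated = filter_labels_by_edge([lab], edges, support_min=0.5)
        assert retained and not eliminated
        assert lab.edge_support == pytest.approx(1.0)

    def test_no_edges_anywhere_eliminates_label(self):
        edges = EdgeMap(data=np.zeros((32, 32, 1), dtype=bool), params=(0, 0.3, 1))
        lab = self._square_label()
        retained, eliminated = filter_labels_by_edge([lab], edges, support_min=0.5)
        assert not retained
        assert eliminated[0].verdict == "weak_edge"
        assert eliminated[0].edge_support == 0.0

    def test_support_min_zero_disables_filter(self):
        edges = EdgeMap(data=np.zeros((32, 32, 1), dtype=bool), params=(0, 0.3, 1))
        retained, eliminated = filter_labels_by_edge(
            [self._square_label()], edges, support_min=0.0
        )
        assert retained and not eliminated
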