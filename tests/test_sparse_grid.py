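"""Free-atom placement, thinning-profile thresholds and NNRMSD."""

import numpy as np
import pytest

from blobid.config import GridConfig
from blobid.density_maps import DensityMap, SyntheticScene, simulate_difference_map
from blobid.errors import EmptyBlobError, EmptyInputError, TooSmallError
from blobid.sparse_grid import (
    ThinningProfile,
    build_sparse_grids,
    connected_cluster,
    detect_thresholds,
    nnrmsd,
    place_free_atoms,
    sigma_profile,
)


def _chain_scene(n=10, resolution=1.2, noise=0.0, seed=0):
    """A bent chain of carbons with bonded spacing."""
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        direction = direction + rng.normal(0, 0.35, 3)
        direction /= np.linalg.norm(direction)
        coords.append(coords[-1] + 1.5 * direction)
    return SyntheticScene(atom_coords=np.array(coords), elements=["C"] * n,
                          resolution=resolution, noise_frac=noise, seed=seed)


class TestPlacement:
    def test_single_atom_first_point_at_maximum(self):
        scene = SyntheticScene(atom_coords=[[0.0, 0.0, 0.0]], elements=["C"],
                               resolution=1.2)
        dmap = simulate_difference_map(scene)
        cloud = place_free_atoms(dmap, np.zeros(3))
        assert len(cloud) >= 1
        assert np.linalg.norm(cloud.points[0]) <= np.max(dmap.spacing) + 1e-9

    def test_chain_cloud_tracks_true_atoms(self):
        scene = _chain_scene(n=10, resolution=1.0)
        dmap = simulate_difference_map(scene)
        cloud = place_free_atoms(dmap, scene.atom_coords.mean(axis=0))
        assert nnrmsd(cloud.points, scene.atom_coords) <= 1.0

    def test_all_zero_map_raises_empty_blob(self):
        dmap = DensityMap(origin=(0, 0, 0), spacing=(0.3, 0.3, 0.3),
                          values=np.zeros((8, 8, 8)))
        with pytest.raises(EmptyBlobError):
            place_free_atoms(dmap, np.array([1.0, 1.0, 1.0]))

    def test_neighbour_window_invariant_many_scenes(self):
        """Every placed atom has a neighbour in [1.2, 1.7] A and all pairs
        are >= 1.2 A apart, over hundreds of random small scenes."""
        cfg = GridConfig()
        checked = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 7))
            coords = rng.uniform(0, 4.5, size=(n, 3))
            scene = SyntheticScene(atom_coords=coords, elements=["C"] * n,
                                   resolution=float(rng.uniform(1.0, 2.5)),
                                   noise_frac=0.05, seed=seed)
            dmap = simulate_difference_map(scene)
            try:
                cloud = place_free_atoms(dmap, coords.mean(axis=0), cfg)
            except EmptyBlobError:
                continue
            pts = cloud.points
            if len(pts) == 1:
                checked += 1
                continue
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= cfg.exclusion - 1e-9
            nearest = d.min(axis=1)
            assert np.all(nearest <= cfg.attach_max + 1e-9)
            assert np.all(nearest >= cfg.attach_min - 1e-9)
            checked += 1
        assert checked >= 190


class TestConnectedCluster:
    def test_selects_group_near_anchor(self, rng):
        a = rng.normal(0, 0.6, (5, 3))
        b = rng.normal(0, 0.6, (5, 3)) + np.array([8.0, 0, 0])
        pts = np.vstack([a, b])
        keep = connected_cluster(pts, np.zeros(3), 2.0)
        assert sorted(keep) == [0, 1, 2, 3, 4]

    def test_chain_below_cutoff_fully_retained(self):
        pts = np.array([[1.9 * i, 0.0, 0.0] for i in range(10)])
        keep = connected_cluster(pts, pts[4], 2.0)
        assert len(keep) == 10

    def test_matches_union_find_oracle(self, rng):
        pts = rng.uniform(0, 8, (100, 3))
        anchor = rng.uniform(0, 8, 3)
        cutoff = 1.6
        parent = list(range(len(pts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) < cutoff:
                    parent[find(i)] = find(j)
        nearest = int(np.argmin(np.linalg.norm(pts - anchor, axis=1)))
        expected = sorted(i for i in range(len(pts)) if find(i) == find(nearest))
        got = sorted(connected_cluster(pts, anchor, cutoff))
        assert got == expected

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            connected_cluster(np.empty((0, 3)), np.zeros(3), 2.0)


class TestSigmaProfile:
    def test_arithmetic_sequence_gives_zero_sigma(self):
        prof = sigma_profile([10, 9, 8, 7, 6])
        np.testing.assert_allclose(prof.sigmas, 0.0, atol=1e-12)

    def test_hand_computed_sample_sd(self):
        # differences after atom 3: (1, 1, 4); sample SD = sqrt(3) = 1.7320508
        prof = sigma_profile([10, 9, 8, 4, 3, 2])
        assert prof.sigmas[0] == pytest.approx(1.7320508, abs=1e-6)

    def test_ascending_input_resorted_descending(self):
        prof = sigma_profile([2, 3, 4, 9, 10, 8])
        assert np.all(np.diff(prof.sorted_densities) <= 0)

    def test_too_few_values_rejected(self):
        with pytest.raises(TooSmallError):
            sigma_profile([3, 2, 1, 0.5])


class TestThresholds:
    def test_flat_sigma_keeps_everything(self):
        prof = ThinningProfile(
            sorted_densities=np.linspace(10, 1, 20),
            sigmas=np.zeros(17),
        )
        out = detect_thresholds(prof)
        assert len(out.thresholds) == 1
        assert out.thresholds[0] <= out.sorted_densities[-1]

    def test_many_peaks_capped_at_five(self):
        n = 80
        sigmas = np.zeros(n)
        for k, pos in enumerate(range(5, 76, 10)):  # 8 well-separated peaks
            sigmas[pos] = 10.0 + k
        prof = ThinningProfile(
            sorted_densities=np.linspace(50, 1, n + 3), sigmas=sigmas
        )
        out = detect_thresholds(prof)
        assert len(out.thresholds) == 5

    def test_matches_windowed_maximum_oracle(self, rng):
        cfg = GridConfig()
        for _ in range(30):
            n = int(rng.integers(12, 60))
            sigmas = rng.uniform(0, 1, n) ** 2
            dens = np.sort(rng.uniform(0, 20, n + 3))[::-1]
            prof = ThinningProfile(sorted_densities=dens, sigmas=sigmas)
            out = detect_thresholds(prof, cfg)
            level = sigmas.mean() + cfg.peak_min_sd * sigmas.std()
            peaks = []
            for i in range(n):
                lo, hi = max(0, i - 3), min(n, i + 4)
                others = [sigmas[j] for j in range(lo, hi) if j != i]
                if sigmas[i] > level and sigmas[i] > max(others):
                    peaks.append(i)
            peaks.sort(key=lambda i: -sigmas[i])
            peaks = peaks[:5]
            if not peaks:
                expected = np.array([dens[-1]])
            else:
                expected = np.array(sorted((dens[i + 3] for i in peaks),
                                           reverse=True))
            np.testing.assert_allclose(out.thresholds, expected)


class TestBuildGrids:
    def test_compact_blob_yields_connected_grids(self):
        scene = _chain_scene(n=8, resolution=1.4, noise=0.03, seed=3)
        dmap = simulate_difference_map(scene)
        grids = build_sparse_grids(dmap, scene.atom_coords.mean(axis=0))
        assert 1 <= len(grids) <= 5
        for g in grids:
            assert g.n_points >= 3
            # 2.3 A single-linkage connectivity
            keep = connected_cluster(g.points, g.points[0], 2.3)
            assert len(keep) == g.n_points

    def test_decoy_density_excluded_by_some_grid(self):
        """With a weaker decoy blob nearby, at least one thinned grid drops
        nearly all decoy-derived points (membership by nearest true atom)."""
        scene = _chain_scene(n=12, resolution=1.6, noise=0.0, seed=7)
        lig = scene.atom_coords
        offset = lig.mean(axis=0) + np.array([0.0, 7.5, 0.0])
        decoys = offset + np.array(
            [[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [1.5, 1.5, 0], [0.7, 0.7, 1.2]],
            dtype=float,
        )
        scene = SyntheticScene(
            atom_coords=lig, elements=list(scene.elements),
            resolution=1.6, noise_frac=0.0, decoys=decoys,
            decoy_elements=["N"] * 5, seed=1,
        )
        dmap = simulate_difference_map(scene)
        grids = build_sparse_grids(dmap, lig.mean(axis=0))
        fractions = []
        for g in grids:
            d_lig = np.min(
                np.linalg.norm(g.points[:, None] - lig[None], axis=2), axis=1
            )
            d_dec = np.min(
                np.linalg.norm(g.points[:, None] - decoys[None], axis=2), axis=1
            )
            n_decoy = int(np.sum(d_dec < d_lig))
            fractions.append(n_decoy / len(decoys))
        assert min(fractions) <= 0.1

    def test_empty_region_raises(self):
        scene = _chain_scene(n=8)
        dmap = simulate_difference_map(scene)
        far = scene.atom_coords.mean(axis=0) + 50.0
        with pytest.raises(EmptyBlobError):
            build_sparse_grids(dmap, far)


class TestNNRMSD:
    def test_identical_sets_zero(self, rng):
        a = rng.normal(size=(7, 3))
        assert nnrmsd(a, a) == 0.0

    def test_single_pair_distance(self):
        assert nnrmsd([[0, 0, 0]], [[0.5, 0, 0]]) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(13, 3))
        d2 = ((a[:, None] - b[None]) ** 2).sum(axis=2)
        expected = np.sqrt(
            (d2.min(axis=1).sum() + d2.min(axis=0).sum()) / (len(a) + len(b))
        )
        assert nnrmsd(a, b) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(10, 3))
        assert nnrmsd(a, b) == pytest.approx(nnrmsd(b, a), abs=1e-12)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-4, 4, 3)
        assert nnrmsd(a @ q.T + t, b @ q.T + t) == pytest.approx(
            nnrmsd(a, b), abs=1e-9
        )

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyInputError):
            nnrmsd(np.empty((0, 3)), np.zeros((2, 3)))
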