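import numpy as np
import pytest
from scipy import ndimage

from alspheno.fractal import (binarize_probability_map, compute_bpf,
                              compute_fd_feature_block,
                              estimate_box_counting_fd,
                              extract_interface_surface, skeletonize_3d,
                              split_hemispheres)
from alspheno.phantoms import generate_phantom
from alspheno.volume import BinaryVolume


class TestBinarize:
    def test_uniform_above_threshold_all_foreground(self):
        vol = binarize_probability_map(np.full((8, 8, 8), 0.6), 0.5)
        assert vol.foreground_count == 512

    def test_ties_are_foreground(self):
        vol = binarize_probability_map(np.full((8, 8, 8), 0.5), 0.5)
        assert vol.foreground_count == 512

    def test_exact_count(self):
        arr = np.full((8, 8, 8), 0.1)
        arr.ravel()[:10] = 0.7
        assert binarize_probability_map(arr, 0.5).foreground_count == 10

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binarize_probability_map(np.full((8, 8, 8), 1.2), 0.5)


class TestSkeletonize:
    def test_solid_tube_thins_to_single_curve(self):
        """A radius-2 solid tube reduces to one 26-connected 1-voxel line."""
        grid = np.zeros((40, 12, 12), dtype=bool)
        yy, zz = np.meshgrid(np.arange(12) - 5.5, np.arange(12) - 5.5,
                             indexing="ij")
        disk = yy ** 2 + zz ** 2 <= 2.0 ** 2
        grid[:, disk] = True
        skel = skeletonize_3d(BinaryVolume(grid))
        struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        _, n_comp = ndimage.label(skel.grid, structure=struct)
        assert n_comp == 1
        # a centreline, not a surface: a small fraction of the input ...
        assert skel.foreground_count <= 60
        # ... at most two voxels per cross-section (diagonal jogs allowed)
        assert skel.grid.sum(axis=(1, 2)).max() <= 2
        # spanning (almost) the whole tube axis
        occupied_slices = (skel.grid.sum(axis=(1, 2)) > 0).sum()
        assert occupied_slices >= 35

    def test_skeleton_is_subset_of_input(self):
        vol = generate_phantom("ball", 32)
        skel = skeletonize_3d(vol)
        assert not (skel.grid & ~vol.grid).any()

    def test_two_tubes_two_components(self):
        grid = np.zeros((40, 20, 12), dtype=bool)
        grid[:, 3:6, 4:7] = True
        grid[:, 13:16, 4:7] = True
        skel = skeletonize_3d(BinaryVolume(grid))
        struct = np.ones((3, 3, 3), dtype=bool)
        _, n_comp = ndimage.label(skel.grid, structure=struct)
        assert n_comp == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_3d(BinaryVolume(np.zeros((8, 8, 8), dtype=bool)))


class TestInterfaceSurface:
    def test_abutting_slabs_contact_face(self):
        wm = np.zeros((32, 32, 16), dtype=bool)
        gm = np.zeros((32, 32, 16), dtype=bool)
        wm[:, :, :8] = True
        gm[:, :, 8:] = True
        surf = extract_interface_surface(BinaryVolume(wm), BinaryVolume(gm))
        assert surf.foreground_count == 32 * 32
        # and it lies on the WM side of the interface
        assert surf.grid[:, :, 7].all()

    def test_disjoint_tissues_empty_surface(self):
        wm = np.zeros((16, 16, 16), dtype=bool)
        gm = np.zeros((16, 16, 16), dtype=bool)
        wm[2:4, 2:4, 2:4] = True
        gm[10:12, 10:12, 10:12] = True
        surf = extract_interface_surface(BinaryVolume(wm), BinaryVolume(gm))
        assert surf.foreground_count == 0

    def test_ball_in_shell_surface_dimension(self):
        """The WM/GM interface of a ball inside a shell is a 2-sphere."""
        size = 64
        ax = np.arange(size) - (size - 1) / 2
        r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
              + ax[None, None, :] ** 2)
        wm = BinaryVolume(r2 <= 20 ** 2)
        gm = BinaryVolume((r2 > 20 ** 2) & (r2 <= 28 ** 2))
        surf = extract_interface_surface(wm, gm)
        fd = estimate_box_counting_fd(surf).fd
        assert abs(fd - 2.0) <= 0.15

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_interface_surface(
                BinaryVolume(np.ones((8, 8, 8), dtype=bool)),
                BinaryVolume(np.ones((8, 8, 9), dtype=bool)))


class TestSplitHemispheres:
    def test_partition_law(self):
        rng = np.random.default_rng(3)
        vol = BinaryVolume(rng.random((17, 12, 12)) < 0.3)
        left, right = split_hemispheres(vol)
        assert not (left.grid & right.grid).any()
        assert np.array_equal(left.grid | right.grid, vol.grid)

    def test_symmetric_volume_even_width_splits_equally(self):
        half = np.random.default_rng(0).random((8, 12, 12)) < 0.4
        grid = np.concatenate([half[::-1], half], axis=0)
        left, right = split_hemispheres(BinaryVolume(grid))
        assert left.foreground_count == right.foreground_count

    def test_object_in_left_half_only(self):
        grid = np.zeros((16, 8, 8), dtype=bool)
        grid[:8, 2:4, 2:4] = True
        left, right = split_hemispheres(BinaryVolume(grid))
        assert right.foreground_count == 0
        assert left.foreground_count == grid.sum()


class TestBoxCountingFD:
    @pytest.mark.parametrize("kind,kwargs,expected,tol", [
        ("line", dict(size=64), 1.0, 0.1),
        ("cube", dict(size=64), 3.0, 0.1),
        ("menger_sponge", dict(level=3), np.log(20) / np.log(3), 0.15),
    ])
    def test_known_dimensions(self, kind, kwargs, expected, tol):
        res = estimate_box_counting_fd(generate_phantom(kind, **kwargs))
        assert abs(res.fd - expected) <= tol

    def test_counts_positive_and_non_increasing(self):
        res = estimate_box_counting_fd(generate_phantom("ball", 48))
        counts = np.array(res.counts)
        assert (counts > 0).all()
        assert (np.diff(counts) <= 0).all()
        assert len(res.box_sizes) >= 3
        assert 0.0 <= res.fit_r2 <= 1.0

    def test_scale_robustness_on_line_and_cube(self):
        for kind in ("line", "cube"):
            fd64 = estimate_box_counting_fd(generate_phantom(kind, 64)).fd
            fd128 = estimate_box_counting_fd(generate_phantom(kind, 128)).fd
            assert abs(fd64 - fd128) < 0.05

    def test_skeleton_fd_below_general_fd_on_solids(self):
        for kind in ("tube", "ball"):
            vol = generate_phantom(kind, 64)
            fd_gen = estimate_box_counting_fd(vol).fd
            fd_skel = estimate_box_counting_fd(skeletonize_3d(vol)).fd
            assert fd_skel <= fd_gen

    def test_empty_and_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_box_counting_fd(
                BinaryVolume(np.zeros((16, 16, 16), dtype=bool)))
        with pytest.raises(ValueError):
            estimate_box_counting_fd(
                BinaryVolume(np.ones((6, 6, 6), dtype=bool)))


class TestBPF:
    def test_direct_formula(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask.ravel()[:100] = True
        wm = np.zeros_like(mask)
        wm.ravel()[:40] = True
        gm = np.zeros_like(mask)
        gm.ravel()[40:90] = True
        bpf_wm, bpf_gm = compute_bpf(BinaryVolume(wm), BinaryVolume(gm),
                                     BinaryVolume(mask))
        assert (bpf_wm, bpf_gm) == (40.0, 50.0)
        assert bpf_wm + bpf_gm <= 100.0

    def test_tissue_outside_mask_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[:4] = True
        wm = np.zeros_like(mask)
        wm[5] = True
        with pytest.raises(ValueError):
            compute_bpf(BinaryVolume(wm),
                        BinaryVolume(np.zeros_like(mask)), BinaryVolume(mask))

    def test_empty_mask_rejected(self):
        empty = BinaryVolume(np.zeros((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError):
            compute_bpf(empty, empty, empty)


@pytest.fixture(scope="module")
def block():
    # mirror-symmetric phantom: elongated WM ellipsoid (its skeleton
    # spans both hemispheres) inside an abutting GM shell
    size = 48
    ax = np.arange(size) - (size - 1) / 2
    xx = ax[:, None, None]
    yy = ax[None, :, None]
    zz = ax[None, None, :]
    f_in = (xx / 14) ** 2 + (yy / 8) ** 2 + (zz / 8) ** 2
    f_out = (xx / 20) ** 2 + (yy / 14) ** 2 + (zz / 14) ** 2
    wm_prob = np.where(f_in <= 1.0, 0.9, 0.05)
    gm_prob = np.where((f_in > 1.0) & (f_out <= 1.0), 0.9, 0.05)
    return compute_fd_feature_block(wm_prob, gm_prob)


class TestFDFeatureBlock:
    def test_exact_name_set(self, block):
        from alspheno import schema
        expected = (schema.fd_feature_names("WM") + schema.fd_feature_names("GM")
                    + ["BPF_WM", "BPF_GM"])
        assert list(block) == expected
        assert len(block) == 20

    def test_left_right_symmetry(self, block):
        for tissue in ("WM", "GM"):
            for rep in ("Gen", "surf", "skel"):
                l = block[f"FD_{tissue}_{rep}_L"]
                r = block[f"FD_{tissue}_{rep}_R"]
                assert abs(l - r) <= 0.05

    def test_fd_values_within_embedding_bounds(self, block):
        for name, v in block.items():
            if name.startswith("FD_"):
                assert 0.0 < v <= 3.0
        assert block["BPF_WM"] + block["BPF_GM"] <= 100.0
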