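"""Registration core: NMI vs brute force, transforms, affine recovery."""

import math

import numpy as np
import pytest

from isatlas.core import OverlapError, Volume
from isatlas.registration import (
    AffineParams,
    BSplineGrid,
    NMIConfig,
    TransformChain,
    apply_transform,
    joint_histogram,
    nmi,
    register_affine,
    register_bspline,
)


def brute_force_nmi(fixed: np.ndarray, moving: np.ndarray, bins: int, exclude_zero_pairs: bool) -> float:
    """Independent NMI oracle: explicit loops over voxels and histogram cells."""
    assert fixed.shape == moving.shape
    flo, fhi = (0.0, 255.0) if fixed.dtype == np.uint8 else (fixed.min(), max(fixed.max(), fixed.min() + 1))
    mlo, mhi = (0.0, 255.0) if moving.dtype == np.uint8 else (moving.min(), max(moving.max(), moving.min() + 1))
    hist = [[0] * bins for _ in range(bins)]
    n = 0
    for i in range(fixed.shape[0]):
        for j in range(fixed.shape[1]):
            for k in range(fixed.shape[2]):
                f, m = float(fixed[i, j, k]), float(moving[i, j, k])
                if exclude_zero_pairs and f == 0 and m == 0:
                    continue
                fb = min(bins - 1, int((f - flo) / (fhi - flo) * bins))
                mb = min(bins - 1, int((m - mlo) / (mhi - mlo) * bins))
                hist[fb][mb] += 1
                n += 1
    h_ab = h_a = h_b = 0.0
    for fb in range(bins):
        pa = sum(hist[fb]) / n
        if pa > 0:
            h_a -= pa * math.log(pa)
        for mb in range(bins):
            p = hist[fb][mb] / n
            if p > 0:
                h_ab -= p * math.log(p)
    for mb in range(bins):
        pb = sum(hist[fb][mb] for fb in range(bins)) / n
        if pb > 0:
            h_b -= pb * math.log(pb)
    if h_ab == 0:
        return 2.0
    return (h_a + h_b) / h_ab


class TestJointHistogram:
    def test_identity_self_pairing_is_diagonal(self):
        data = np.arange(27, dtype=np.float64).reshape(3, 3, 3)
        vol = Volume(data, 1.0)
        cfg = NMIConfig(bins=27, exclude_zero_pairs=False, interpolation="nearest")
        h = joint_histogram(vol, vol, TransformChain.identity(), cfg)
        assert h.sum() == 27
        assert np.all(h == np.diag(np.diag(h)))

    def test_hand_enumerated_counts(self):
        fixed = Volume(np.array([[[0], [255]], [[0], [255]]], dtype=np.uint8), 1.0)
        moving = Volume(np.full((2, 2, 1), 255, dtype=np.uint8), 1.0)
        cfg = NMIConfig(bins=2, exclude_zero_pairs=False, interpolation="nearest")
        h = joint_histogram(fixed, moving, TransformChain.identity(), cfg)
        assert h[0, 1] == 2 and h[1, 1] == 2 and h.sum() == 4
        # entropy arithmetic from those counts: H_A=ln2, H_B=0, H_AB=ln2
        score = nmi(fixed, moving, TransformChain.identity(), cfg)
        assert score == pytest.approx((math.log(2) + 0.0) / math.log(2), abs=1e-12)

    def test_no_overlap_raises(self):
        vol = Volume(np.ones((4, 4, 4)), 1.0)
        far = TransformChain(AffineParams(t=(1000.0, 0.0, 0.0)))
        with pytest.raises(OverlapError):
            joint_histogram(vol, vol, far, NMIConfig(exclude_zero_pairs=False))


class TestNMI:
    def test_perfect_dependence_is_two(self, template_32):
        vol = template_32[0]
        assert nmi(vol, vol) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("exclude", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_small_grids(self, seed, exclude):
        r = np.random.default_rng(seed)
        fixed = Volume(r.integers(0, 256, (6, 5, 4)).astype(np.uint8), 1.0)
        moving = Volume(r.integers(0, 256, (6, 5, 4)).astype(np.uint8), 1.0)
        cfg = NMIConfig(bins=8, exclude_zero_pairs=exclude, interpolation="nearest")
        ours = nmi(fixed, moving, TransformChain.identity(), cfg)
        oracle = brute_force_nmi(fixed.data, moving.data, 8, exclude)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_under_identity(self):
        r = np.random.default_rng(7)
        a = Volume(r.integers(0, 256, (8, 8, 8)).astype(np.uint8), 1.0)
        b = Volume(r.integers(0, 256, (8, 8, 8)).astype(np.uint8), 1.0)
        cfg = NMIConfig(bins=16, exclude_zero_pairs=False, interpolation="nearest")
        assert nmi(a, b, None, cfg) == pytest.approx(nmi(b, a, None, cfg), abs=1e-12)

    def test_independent_volumes_score_near_one(self):
        r = np.random.default_rng(3)
        a = Volume(r.integers(0, 256, (64, 64, 64)).astype(np.uint8), 1.0)
        b = Volume(r.integers(0, 256, (64, 64, 64)).astype(np.uint8), 1.0)
        cfg = NMIConfig(bins=32, exclude_zero_pairs=False, interpolation="nearest")
        assert nmi(a, b, None, cfg) <= 1.02


class TestApplyTransform:
    def test_identity_is_bit_exact(self, template_32):
        vol = template_32[0]
        out = apply_transform(vol, TransformChain.identity())
        assert np.array_equal(out.data, vol.data)

    def test_integer_translation_moves_delta_exactly(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        vol = Volume(data, 2.0)
        # chain maps fixed->moving: output(x) = input(x + 2 voxels in x)
        chain = TransformChain(AffineParams(t=(4.0, 0.0, 0.0)))
        out = apply_transform(vol, chain, "linear")
        expect = np.zeros((9, 9, 9))
        expect[2, 4, 4] = 100.0  # per-voxel oracle: index arithmetic
        assert np.allclose(out.data, expect, atol=1e-9)

    def test_labels_require_nearest_and_conserve_ids(self, template_32):
        labels = template_32[1]
        with pytest.raises(ValueError):
            apply_transform(labels, TransformChain.identity(), "linear")
        chain = TransformChain(
            AffineParams(t=(3.0, -2.0, 1.0), r=(0.05, -0.1, 0.2), dof=6, center=(60.0, 60.0, 60.0))
        )
        out = apply_transform(labels, chain)
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))

    def test_forward_then_inverse_affine_recovers_smooth_volume(self, template_32):
        from scipy import ndimage
        vol = Volume(ndimage.gaussian_filter(template_32[0].data.astype(np.float64), 2.0), 3.9)
        center = tuple((n - 1) * 3.9 / 2 for n in vol.shape)
        fwd = AffineParams(t=(3.9, -7.8, 3.9), r=(0.1, 0.05, -0.08), dof=6, center=center)
        M = np.linalg.inv(fwd.matrix())
        a = apply_transform(vol, TransformChain(fwd), "linear")
        # apply the exact inverse matrix via a raw-matrix chain
        class _Raw:
            def __init__(self, M):
                self.M = M
            def map_points(self, phys):
                flat = phys.reshape(3, -1)
                out = self.M[:3, :3] @ flat + self.M[:3, 3:4]
                return out.reshape(phys.shape)
        b = apply_transform(a, _Raw(M), "linear")
        interior = (slice(6, -6),) * 3
        err = np.abs(b.data[interior] - vol.data[interior])
        assert err.mean() <= 2.0


class TestBSplineGrid:
    def test_chain_serialization_round_trips(self, tmp_path):
        grid = BSplineGrid.for_domain((100.0, 80.0, 60.0), 20.0, (2.0, 2.0, 2.0))
        grid.coeffs[:] = np.random.default_rng(0).normal(0, 2, grid.coeffs.shape).round(6)
        chain = TransformChain(
            AffineParams(t=(1.0, 2.0, 3.0), r=(0.1, 0.2, 0.3), s=(1.1, 0.9, 1.0), h=(0.01, 0.0, 0.02), dof=12),
            [grid],
        )
        path = tmp_path / "chain.json"
        chain.save(path)
        loaded = TransformChain.load(path)
        pts = np.random.default_rng(1).uniform(0, 60, (3, 50))
        assert np.allclose(chain.map_points(pts), loaded.map_points(pts), atol=1e-8)

    def test_spacing_below_four_voxels_rejected(self):
        with pytest.raises(ValueError):
            BSplineGrid.for_domain((100.0, 100.0, 100.0), 5.0, (2.0, 2.0, 2.0))


class TestRegisterAffine:
    def test_self_registration_stays_at_identity(self, template_32):
        vol = template_32[0]
        est, score = register_affine(vol, vol, dof=6, levels=(2, 1))
        v = vol.voxel_size[0]
        assert np.all(np.abs(est.t) <= 0.25 * v)
        assert np.all(np.rad2deg(np.abs(est.r)) <= 0.5)

    def test_known_translation_recovered(self, template_32):
        vol = template_32[0]
        v = vol.voxel_size[0]
        gt = AffineParams(t=(5 * v, 0.0, 0.0), dof=6)
        moving = apply_transform(vol, TransformChain(gt), "linear")
        est, _ = register_affine(vol, moving, dof=6, levels=(2, 1))
        # est composed with gt should be identity
        M = est.matrix() @ gt.matrix()
        assert np.all(np.abs(M[:3, 3] / v) <= 0.5)

    def test_rotation_and_scale_recovered(self, template_32):
        vol = template_32[0]
        v = vol.voxel_size[0]
        center = tuple((n - 1) * v / 2 for n in vol.shape)
        gt = AffineParams(r=(0.0, 0.0, np.deg2rad(8.0)), s=(1.05,) * 3, dof=9, center=center)
        moving = apply_transform(vol, TransformChain(gt), "linear")
        e6, _ = register_affine(vol, moving, dof=6, levels=(2, 1))
        est, _ = register_affine(vol, moving, dof=9, init=e6, levels=(2, 1))
        M = (est.matrix() @ gt.matrix())[:3, :3]
        s = np.linalg.svd(M, compute_uv=False)
        assert np.all(np.abs(s - 1) <= 0.02)
        U, _, Vt = np.linalg.svd(M)
        ang = np.degrees(np.arccos(np.clip((np.trace(U @ Vt) - 1) / 2, -1, 1)))
        assert ang <= 1.0

    def test_score_never_below_init(self, template_32):
        vol = template_32[0]
        moving = apply_transform(
            vol, TransformChain(AffineParams(t=(7.8, -3.9, 0.0))), "linear"
        )
        init = AffineParams(t=(-7.8, 3.9, 0.0), dof=6)
        cfg = NMIConfig()
        est, score = register_affine(vol, moving, dof=6, init=init, levels=(1,))
        init_score = nmi(vol, moving, TransformChain(init), cfg)
        assert score >= init_score - 1e-9


class TestRegisterBspline:
    def test_null_deformation_on_identical_images(self, template_32):
        vol = template_32[0]
        chain = TransformChain.identity()
        grid, _ = register_bspline(vol, vol, chain, 8 * 3.9, sample_stride=1)
        assert np.max(np.abs(grid.coeffs)) <= 0.25 * 3.9

    def test_objective_never_decreases_from_init(self, masked_cohort_48):
        from isatlas.registration import elastic_objective_score
        cohort, _ = masked_cohort_48
        fixed, moving = cohort.volumes[0], cohort.volumes[1]
        e6, _ = register_affine(fixed, moving, dof=6)
        chain = TransformChain(e6)
        before = elastic_objective_score(fixed, moving, chain)
        grid, after = register_bspline(fixed, moving, chain, 12 * 3.9)
        assert after >= before - 1e-9
        full = elastic_objective_score(fixed, moving, chain.with_grid(grid))
        assert full == pytest.approx(after, abs=1e-6)
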