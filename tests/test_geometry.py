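"""ROI construction, dose resampling and dose-volume features."""

import numpy as np
import pytest

from dosederm.core import ImageGrid, StructureMask
from dosederm.geometry import (
    build_body_mask,
    build_skin5mm,
    build_v5gy_roi,
    compute_dvh_features,
    resample_dose_to_ct,
)


def _ellipse_ct(shape=(8, 40, 40), spacing=(2.5, 2.0, 2.0)):
    z, y, x = np.indices(shape)
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    inside = ((y - cy) / 15) ** 2 + ((x - cx) / 18) ** 2 <= 1.0
    hu = np.where(inside, 40.0, -1000.0)
    return ImageGrid(hu, spacing=spacing), inside


class TestBodyMask:
    def test_threshold_separates_phantom_from_air(self):
        ct, inside = _ellipse_ct()
        body = build_body_mask(ct)
        assert np.array_equal(body.mask, inside)

    def test_internal_lung_included_after_hole_fill(self):
        ct, inside = _ellipse_ct()
        lung = np.zeros(ct.shape, dtype=bool)
        lung[2:6, 15:25, 15:25] = True
        ct.values[lung] = -750.0
        body = build_body_mask(ct)
        assert np.array_equal(body.mask, inside)  # lung voxels filled back in

    def test_largest_component_matches_brute_force_labeling(self, rng):
        vol = rng.random((10, 12, 12)) > 0.7
        ct = ImageGrid(np.where(vol, 100.0, -1000.0), spacing=(1, 1, 1))
        body = build_body_mask(ct)
        # brute-force 26-connected flood fill
        seen = np.zeros_like(vol)
        best = set()
        for start in np.argwhere(vol):
            s = tuple(start)
            if seen[s]:
                continue
            comp, stack = set(), [s]
            seen[s] = True
            while stack:
                v = stack.pop()
                comp.add(v)
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            w = (v[0] + dz, v[1] + dy, v[2] + dx)
                            if all(0 <= w[a] < vol.shape[a] for a in range(3)) \
                                    and vol[w] and not seen[w]:
                                seen[w] = True
                                stack.append(w)
            if len(comp) > len(best):
                best = comp
        # oracle = largest component plus per-slice hole fill (flood the
        # background from the slice border; unreached voxels are holes)
        comp_mask = np.zeros_like(vol)
        for v in best:
            comp_mask[v] = True
        oracle = np.zeros_like(vol)
        for k in range(vol.shape[0]):
            sl = comp_mask[k]
            reached = np.zeros_like(sl)
            stack = [(i, j) for i in range(sl.shape[0]) for j in range(sl.shape[1])
                     if (i in (0, sl.shape[0] - 1) or j in (0, sl.shape[1] - 1))
                     and not sl[i, j]]
            for s in stack:
                reached[s] = True
            while stack:
                i, j = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    w = (i + di, j + dj)
                    if 0 <= w[0] < sl.shape[0] and 0 <= w[1] < sl.shape[1] \
                            and not sl[w] and not reached[w]:
                        reached[w] = True
                        stack.append(w)
            oracle[k] = sl | (~reached & ~sl)
        assert np.array_equal(body.mask, oracle)

    def test_empty_raises(self):
        ct = ImageGrid(np.full((3, 3, 3), -1000.0), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="no body found"):
            build_body_mask(ct)


class TestSkin5mm:
    def test_digital_sphere_matches_all_pairs_distance_oracle(self):
        shape, spacing = (25, 25, 25), (1.0, 1.0, 1.0)
        z, y, x = np.indices(shape)
        body = ((z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2) <= 10 ** 2
        skin = build_skin5mm(StructureMask("b", body), spacing, depth_mm=5.0)
        inside = np.argwhere(body).astype(float)
        outside = np.argwhere(~body).astype(float)
        dmin = np.full(len(inside), np.inf)
        for chunk in np.array_split(outside, 10):
            d = np.sqrt(((inside[:, None, :] - chunk[None, :, :]) ** 2).sum(-1))
            dmin = np.minimum(dmin, d.min(axis=1))
        oracle = np.zeros(shape, dtype=bool)
        for (v, dm) in zip(inside.astype(int), dmin):
            oracle[tuple(v)] = dm <= 5.0 + 1e-9
        assert np.array_equal(skin.mask, oracle)

    def test_thin_body_saturates(self):
        body = np.zeros((4, 10, 10), dtype=bool)
        body[:, 4:6, :] = True  # 4 mm thick slab at 2 mm spacing
        skin = build_skin5mm(StructureMask("b", body), (2.0, 2.0, 2.0))
        assert np.array_equal(skin.mask, body)

    def test_empty_body(self):
        skin = build_skin5mm(StructureMask("b", np.zeros((3, 3, 3), bool)),
                             (1, 1, 1))
        assert skin.mask.sum() == 0


class TestDoseResampling:
    def test_identity_on_identical_grids(self, rng):
        g = ImageGrid(rng.random((5, 8, 8)), spacing=(2, 2, 2), origin=(0, 0, 0))
        out = resample_dose_to_ct(g, ImageGrid(np.zeros((5, 8, 8)),
                                               spacing=(2, 2, 2), origin=(0, 0, 0)))
        assert np.allclose(out.values, g.values)

    def test_affine_field_reproduced_exactly(self):
        # trilinear interpolation reproduces affine fields
        nz, ny, nx = 6, 10, 10
        zc = np.arange(nz) * 3.0
        xc = np.arange(nx) * 2.0
        dose_vals = 0.5 * xc[None, None, :] + 0.2 * zc[:, None, None] \
            + np.zeros((1, ny, 1))
        dose = ImageGrid(np.broadcast_to(dose_vals, (nz, ny, nx)).copy(),
                         spacing=(3, 2, 2), origin=(0, 0, 0))
        ct = ImageGrid(np.zeros((4, 6, 6)), spacing=(1.5, 1.0, 1.0),
                       origin=(1.5, 2.0, 3.0))
        out = resample_dose_to_ct(dose, ct)
        zc2, _, xc2 = ct.axis_centers()
        expect = 0.5 * xc2[None, None, :] + 0.2 * zc2[:, None, None] \
            + np.zeros((1, 6, 1))
        assert np.allclose(out.values, np.broadcast_to(expect, out.shape))

    def test_matches_trilinear_formula_per_voxel(self, rng):
        dose = ImageGrid(rng.random((6, 7, 7)), spacing=(2.0, 3.0, 3.0),
                         origin=(-1.0, 0.5, -0.5))
        ct = ImageGrid(np.zeros((3, 4, 4)), spacing=(1.7, 2.3, 2.1),
                       origin=(0.3, 2.2, 1.9))
        out = resample_dose_to_ct(dose, ct)
        for v in [(0, 0, 0), (1, 2, 3), (2, 3, 1)]:
            w = ct.world_coords(v)
            f = (np.asarray(w) - dose.origin) / dose.spacing
            i0 = np.floor(f).astype(int)
            t = f - i0
            acc = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        wgt = ((t[0] if dz else 1 - t[0])
                               * (t[1] if dy else 1 - t[1])
                               * (t[2] if dx else 1 - t[2]))
                        acc += wgt * dose.values[i0[0] + dz, i0[1] + dy, i0[2] + dx]
            assert out.values[v] == pytest.approx(acc, rel=1e-10)

    def test_disjoint_extents_rejected(self):
        dose = ImageGrid(np.zeros((2, 2, 2)), spacing=(1, 1, 1), origin=(100, 100, 100))
        ct = ImageGrid(np.zeros((2, 2, 2)), spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.raises(ValueError, match="no overlap"):
            resample_dose_to_ct(dose, ct)


class TestV5GyRoi:
    def _setup(self):
        skin = np.zeros((4, 10, 10), dtype=bool)
        skin[:, 2:8, 2:8] = True
        return StructureMask("skin5mm", skin)

    def test_zero_dose_empty(self):
        skin = self._setup()
        dose = ImageGrid(np.zeros((4, 10, 10)), spacing=(1, 1, 1))
        assert build_v5gy_roi(skin, dose, 50.0).mask.sum() == 0

    def test_full_dose_equals_skin(self):
        skin = self._setup()
        dose = ImageGrid(np.full((4, 10, 10), 50.0), spacing=(1, 1, 1))
        assert np.array_equal(build_v5gy_roi(skin, dose, 50.0).mask, skin.mask)

    def test_half_space_conjunction_count(self, rng):
        skin = self._setup()
        vals = np.zeros((4, 10, 10))
        vals[:, :, 5:] = 10.0  # half space above the 5 Gy threshold
        dose = ImageGrid(vals, spacing=(1, 1, 1))
        roi = build_v5gy_roi(skin, dose, 50.0)
        brute = sum(1 for v in np.argwhere(skin.mask) if vals[tuple(v)] >= 5.0)
        assert roi.mask.sum() == brute

    def test_invalid_fraction(self):
        skin = self._setup()
        dose = ImageGrid(np.zeros((4, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="invalid fraction"):
            build_v5gy_roi(skin, dose, 50.0, fraction=0.0)


class TestDvhFeatures:
    def test_uniform_step_dose(self):
        mask = np.zeros((4, 10, 10), dtype=bool)
        mask[0, :5, :5] = True
        mask[1, :5, :5] = True
        mask[2, :5, :5] = True
        mask[3, :5, :5] = True  # 100 voxels
        skin = StructureMask("skin5mm", mask)
        spacing = (2.5, 2.0, 2.0)  # 0.01 cc voxels
        dose = ImageGrid(np.full((4, 10, 10), 10.0), spacing=spacing)
        ptv = StructureMask("ptv", np.zeros((4, 10, 10), bool))
        ptv.mask[0, 0, 0] = True
        f = compute_dvh_features(dose, skin, ptv, prescription=50.0)
        assert f.skin5mm_v[5] == pytest.approx(1.0)
        assert f.skin5mm_v[10] == pytest.approx(1.0)
        assert f.skin5mm_v[15] == 0.0

    def test_linear_gradient_analytic_fraction(self):
        n = 200
        mask = np.ones((1, 1, n), dtype=bool)
        dose = ImageGrid(np.linspace(0, 50, n).reshape(1, 1, n),
                         spacing=(10.0, 10.0, 1.0))
        skin = StructureMask("skin5mm", mask)
        ptv = StructureMask("ptv", mask)
        f = compute_dvh_features(dose, skin, ptv, prescription=50.0)
        total = mask.sum() * 0.1  # cc
        for x in (5, 10, 25, 40):
            assert f.skin5mm_v[x] == pytest.approx((1 - x / 50) * total, rel=0.02)

    def test_hot_ptv_saturation(self):
        mask = np.ones((2, 4, 4), dtype=bool)
        dose = ImageGrid(np.full((2, 4, 4), 52.5), spacing=(2.5, 2, 2))
        skin = StructureMask("skin5mm", mask)
        ptv = StructureMask("ptv", mask)
        f = compute_dvh_features(dose, skin, ptv, prescription=50.0)
        vol = mask.sum() * dose.voxel_volume_cc
        assert f.ptv105 == pytest.approx(vol)
        assert f.ptv100 == pytest.approx(vol)

    def test_monotone_over_random_fields(self, rng):
        for _ in range(5):
            mask = rng.random((4, 8, 8)) > 0.4
            dose = ImageGrid(rng.uniform(0, 60, (4, 8, 8)), spacing=(2.5, 2, 2))
            skin = StructureMask("skin5mm", mask)
            ptv = StructureMask("ptv", mask)
            f = compute_dvh_features(dose, skin, ptv, 50.0)
            vs = [f.skin5mm_v[x] for x in range(5, 55, 5)]
            assert all(a >= b for a, b in zip(vs, vs[1:]))
            assert all(0 <= v <= skin.volume_cc(dose) + 1e-9 for v in vs)

    def test_resolution_robustness_on_smooth_field(self):
        # doubling voxel volume changes V_x by < 5% for a smooth dose
        n = 64
        z, y, x = np.indices((8, n, n)).astype(float)
        field = 50.0 * np.exp(-((x - n / 2) ** 2 + (y - n / 2) ** 2) / (n * 4))
        mask = np.ones((8, n, n), dtype=bool)
        fine = compute_dvh_features(
            ImageGrid(field, spacing=(2.5, 1, 1)),
            StructureMask("s", mask), StructureMask("p", mask), 50.0)
        coarse = compute_dvh_features(
            ImageGrid(field[:, ::2, :], spacing=(2.5, 2, 1)),
            StructureMask("s", mask[:, ::2, :]),
            StructureMask("p", mask[:, ::2, :]), 50.0)
        for xgy in (5, 15, 25, 35):
            assert coarse.skin5mm_v[xgy] == pytest.approx(fine.skin5mm_v[xgy],
                                                          rel=0.05)

    def test_grid_mismatch(self):
        dose = ImageGrid(np.zeros((2, 2, 2)), spacing=(1, 1, 1))
        skin = StructureMask("s", np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match="grid mismatch"):
            compute_dvh_features(dose, skin, skin, 50.0)


def test_roi_set_inclusions_on_cohort(small_cohort):
    """v5gy <= skin5mm <= body on every generated patient."""
    from dosederm.geometry import build_roi_set

    for p in small_cohort.patients[:4]:
        dose_ct = resample_dose_to_ct(p.dose, p.ct)
        rois = build_roi_set(p.ct, p.ptv, dose_ct, 50.0)
        assert not np.any(rois.skin5mm.mask & ~rois.body.mask)
        assert not np.any(rois.v5gy.mask & ~rois.skin5mm.mask)
        assert np.array_equal(rois.v5gy.mask,
                              rois.skin5mm.mask & rois.isodose5.mask)
        assert not np.any(rois.ptv100_region.mask & ~rois.ptv.mask)
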