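"""Chest-wall tracing and view bisection: analytic edges, pixel-count
oracles, and the partition-of-unity invariant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import rotate as sk_rotate

import mammoquad as mq
from mammoquad.errors import ChestWallTraceError, InputError, LandmarkError
from mammoquad.geometry import ChestWallBoundary

from conftest import small_phantom_spec


def edge_image(slope, c0=40.0, size=160, muscle=220.0, fat=100.0):
    """Synthetic MLO-like image whose muscle/fat interface is the straight
    line col = c0 + slope*row (muscle on the low-column side)."""
    rr = np.arange(size)[:, None]
    cc = np.arange(size)[None, :]
    px = np.where(cc < c0 + slope * rr, muscle, fat).astype(float)
    return mq.MammogramImage(px, view="MLO", laterality="L",
                             pixel_spacing=0.5)


def half_ellipse_mask(size=160, b=60, a=90):
    rr = np.arange(size)[:, None]
    cc = np.arange(size)[None, :]
    cy = (size - 1) / 2.0  # half-integer center: mirror-symmetric raster
    return (cc / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0


class TestTraceChestWall:
    def test_vertical_edge(self):
        img = edge_image(slope=0.0, c0=40.0)
        bnd = mq.trace_chest_wall(img, (80, 40))
        # every traced point within 1 px of the true column
        assert np.all(np.abs(bnd.traced_points[:, 1] - 39.5) <= 1.0)
        # edge line vertical within 1 degree
        _, d = bnd.edge_line
        angle = np.degrees(np.arccos(abs(d[0])))
        assert angle <= 1.0

    @pytest.mark.parametrize("slope", [0.3, -0.45, 0.6])
    def test_oblique_edge_slope_recovered(self, slope):
        img = edge_image(slope=slope, c0=70.0)
        bnd = mq.trace_chest_wall(img, (80, int(70 + slope * 80)))
        _, d = bnd.edge_line
        fitted = d[1] / d[0]  # dcol/drow
        assert fitted == pytest.approx(slope, rel=0.02, abs=0.01)

    def test_seed_in_homogeneous_fat_fails(self):
        img = edge_image(slope=0.0, c0=40.0)
        with pytest.raises(ChestWallTraceError):
            mq.trace_chest_wall(img, (80, 120))  # deep inside fat

    def test_seed_outside_image(self):
        img = edge_image(slope=0.0)
        with pytest.raises(InputError):
            mq.trace_chest_wall(img, (500, 40))

    def test_spline_residual_bound(self):
        img = edge_image(slope=0.4, c0=60.0)
        bnd = mq.trace_chest_wall(img, (80, int(60 + 0.4 * 80)))
        rows, cols = bnd.traced_points[:, 0], bnd.traced_points[:, 1]
        resid = np.abs(bnd.col_at(rows) - cols)
        assert resid.max() <= 3.0

    def test_exclude_muscle_on_phantom(self):
        img, truth = mq.generate_phantom(
            small_phantom_spec("MLO", noise_sd=0.0, seed=9))
        fg, _ = mq.segment_breast(img, seed=0)
        bnd = mq.trace_chest_wall(img, truth.chest_wall_seed_point)
        mask = mq.exclude_muscle(fg, bnd)
        # muscle nearly fully removed, breast nearly fully kept
        assert (mask & truth.muscle_mask).sum() <= 0.02 * truth.muscle_mask.sum()
        assert (truth.breast_mask & ~mask).sum() <= 0.01 * truth.breast_mask.sum()


class TestBisectCC:
    def test_symmetric_breast_equal_halves(self):
        mask = half_ellipse_mask()
        part = mq.bisect_cc(mask, (79.5, 89), "L")
        a, b = (part.masks[k].sum() for k in ("CC-L", "CC-M"))
        assert abs(a - b) / mask.sum() < 0.01

    def test_shifted_nipple_conserves_union(self):
        mask = half_ellipse_mask()
        up = mq.bisect_cc(mask, (60, 80), "L")
        down = mq.bisect_cc(mask, (100, 80), "L")
        for part in (up, down):
            assert (part.masks["CC-L"] | part.masks["CC-M"]).sum() == mask.sum()
        assert up.masks["CC-L"].sum() < down.masks["CC-L"].sum()

    def test_pixel_count_oracle(self, rng):
        """Half-plane areas equal brute-force per-pixel counting."""
        mask = half_ellipse_mask()
        for _ in range(5):
            nr = int(rng.integers(30, 130))
            part = mq.bisect_cc(mask, (nr, 60), "L")
            rows, cols = np.nonzero(mask)
            above = int(np.sum(rows <= nr))
            assert part.masks["CC-L"].sum() == above
            assert part.masks["CC-M"].sum() == mask.sum() - above

    def test_laterality_flips_labels(self):
        mask = half_ellipse_mask()
        left = mq.bisect_cc(mask, (70, 80), "L")
        right = mq.bisect_cc(mask, (70, 80), "R")
        # same geometry, swapped labels (up to the on-line tie pixels)
        assert abs(int(left.masks["CC-L"].sum())
                   - int(right.masks["CC-M"].sum())) <= mask[70, :].sum()

    def test_mirror_consistency(self):
        """Flipping the image vertically and swapping laterality swaps the
        medial/lateral labels but leaves the areas unchanged."""
        rng = np.random.default_rng(3)
        mask = half_ellipse_mask() & (rng.random((160, 160)) < 0.9)
        nr = 70
        orig = mq.bisect_cc(mask, (nr, 80), "L")
        flipped = mq.bisect_cc(mask[::-1], (159 - nr, 80), "R")
        assert orig.masks["CC-L"].sum() == flipped.masks["CC-L"].sum()
        assert orig.masks["CC-M"].sum() == flipped.masks["CC-M"].sum()

    def test_nipple_outside_breast_rejected(self):
        mask = half_ellipse_mask()
        with pytest.raises(LandmarkError):
            mq.bisect_cc(mask, (5, 155), "L")


def straight_boundary(point, direction):
    """Minimal ChestWallBoundary for a known straight edge line."""
    point = np.asarray(point, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    traced = np.array([point - 40 * d, point, point + 40 * d])
    return ChestWallBoundary(
        seed_point=(int(point[0]), int(point[1])),
        traced_points=traced[np.argsort(traced[:, 0])],
        spline_control_points=traced,
        edge_line=(point, d if d[0] > 0 else -d),
    )


class TestBisectMLO:
    def test_vertical_edge_reduces_to_cc(self):
        mask = half_ellipse_mask()
        bnd = straight_boundary((80, 10), (1.0, 0.0))
        part = mq.bisect_mlo(mask, (80, 89), bnd)
        cc = mq.bisect_cc(mask, (80, 89), "L")
        np.testing.assert_array_equal(part.masks["MLO-S"], cc.masks["CC-L"])
        np.testing.assert_array_equal(part.masks["MLO-I"], cc.masks["CC-M"])

    def test_bisector_perpendicular_to_edge(self):
        bnd = straight_boundary((80, 40), (1.0, 1.0))
        mask = half_ellipse_mask()
        part = mq.bisect_mlo(mask, (80, 80), bnd)
        _, bd = part.bisecting_line
        _, ed = bnd.edge_line
        assert abs(float(bd @ ed)) < 1e-9

    def test_signed_distance_oracle(self):
        """Partition equals a brute-force per-pixel signed-offset
        classification for an oblique edge."""
        mask = half_ellipse_mask()
        bnd = straight_boundary((80, 30), (1.0, -0.5))
        nip = (84.0, 88.0)
        part = mq.bisect_mlo(mask, nip, bnd)
        _, d = bnd.edge_line
        top = bnd.traced_points[0]
        sign = 1.0 if ((top[0] - nip[0]) * d[0]
                       + (top[1] - nip[1]) * d[1]) >= 0 else -1.0
        n_sup = 0
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows, cols):
            s = (r - nip[0]) * d[0] + (c - nip[1]) * d[1]
            if sign * s >= 0:
                n_sup += 1
        assert int(part.masks["MLO-S"].sum()) == n_sup
        assert int(part.masks["MLO-I"].sum()) == mask.sum() - n_sup

    def test_rotation_leaves_areas_invariant(self):
        """Rotating the mask, nipple and edge line together changes the
        partition areas by < 0.5% (raster discretisation only)."""
        # ellipse well inside the rotation circle so no pixel clips out
        rr = np.arange(200)[:, None]
        cc = np.arange(200)[None, :]
        mask = ((cc - 90) / 55.0) ** 2 + ((rr - 100) / 55.0) ** 2 <= 1.0
        nip = (100.0, 120.0)
        bnd = straight_boundary((100, 45), (1.0, -0.3))
        base = mq.bisect_mlo(mask, nip, bnd)
        n0 = mask.sum()
        for theta in (10.0, 25.0):
            rot = sk_rotate(mask.astype(float), theta, center=(100, 100),
                            order=0) > 0.5
            t = np.radians(theta)
            # skimage's rotate maps p -> R(p - ctr) + ctr with this R in
            # (row, col) coordinates (verified against a marker pixel)
            R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            ctr = np.array([100.0, 100.0])
            nip_r = R @ (np.array(nip) - ctr) + ctr
            d_r = R @ bnd.edge_line[1]
            p_r = R @ (bnd.edge_line[0] - ctr) + ctr
            bnd_r = straight_boundary(p_r, d_r)
            part = mq.bisect_mlo(rot, tuple(nip_r), bnd_r)
            frac_base = base.masks["MLO-S"].sum() / n0
            frac_rot = part.masks["MLO-S"].sum() / rot.sum()
            assert abs(frac_base - frac_rot) < 0.005


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    nr=st.integers(min_value=25, max_value=135),
    nc=st.integers(min_value=5, max_value=85),
    dcol=st.floats(min_value=-0.8, max_value=0.8),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_partition_of_unity(nr, nc, dcol, seed):
    """For any nipple position and edge angle, the two partitions tile the
    breast mask exactly (CC and MLO)."""
    rng = np.random.default_rng(seed)
    mask = half_ellipse_mask() & (rng.random((160, 160)) < 0.95)
    if not mask[max(nr - 5, 0):nr + 5, :].any():
        return
    cc = mq.bisect_cc(mask, (nr, nc), "L")
    assert not (cc.masks["CC-L"] & cc.masks["CC-M"]).any()
    np.testing.assert_array_equal(cc.masks["CC-L"] | cc.masks["CC-M"], mask)

    bnd = straight_boundary((80, 20), (1.0, dcol))
    mlo = mq.bisect_mlo(mask, (nr, nc), bnd)
    assert not (mlo.masks["MLO-S"] & mlo.masks["MLO-I"]).any()
    np.testing.assert_array_equal(mlo.masks["MLO-S"] | mlo.masks["MLO-I"],
                                  mask)
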