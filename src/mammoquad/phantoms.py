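"""Mammogram phantoms with exact ground truth.

The generator produces the simplest geometry that exercises every downstream
operation, not anatomically realistic texture:

* CC view — the breast profile is a half-ellipse attached to the left image
  edge (the chest wall); no pectoral muscle.
* MLO view — the same half-ellipse, with an oblique pectoral wedge along the
  chest edge: all ellipse pixels left of a straight line from
  ``(0, muscle_top_col)`` to ``(muscle_bottom_row, 0)`` are muscle.

Dense (fibroglandular) tissue is a set of hard-edged, non-overlapping disks
placed fully inside the breast, so the ground-truth dense area is exact
before noise. Disks alternate between two intensity sub-levels (``dense``
and ``dense + dense_split``) to emulate heterogeneous fibroglandular tissue;
this gives the piecewise-constant phantom enough distinct gray levels for
the 4-cluster outer / 3-cluster inner FCM even at zero noise. Setting
``dense_split=0`` collapses them to a single level.

Pixel intensities are piecewise constant per tissue plus i.i.d. Gaussian
noise, clipped to ``[0, max_gray]``. Ground-truth masks are pre-noise exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SizingError
from .image import MammogramImage

__all__ = ["PhantomSpec", "PhantomGroundTruth", "generate_phantom"]


@dataclass
class PhantomSpec:
    """Parameters of one phantom acquisition.

    ``breast_semi_axes`` is ``(vertical, horizontal)`` in pixels: the
    half-ellipse spans ``2*vertical`` rows centred on the frame and extends
    ``horizontal`` columns from the chest edge. ``nipple_position`` in
    (0, 1) places the nipple along the anterior contour (0 = superior end,
    0.5 = anterior-most point, 1 = inferior end). ``blob_region`` optionally
    confines dense-disk centres to the superior ('top') or inferior
    ('bottom') half, which is useful for constructing cohorts with a known
    quadrant of maximal density.
    """

    view: str = "CC"
    laterality: str = "L"
    image_height: int = 256
    image_width: int = 256
    pixel_spacing: float = 0.5  # mm / pixel
    breast_semi_axes: tuple[int, int] = (110, 160)
    nipple_position: float = 0.5
    n_dense_blobs: int = 6
    blob_radius_range: tuple[int, int] = (6, 14)
    intensity_levels: dict = field(
        default_factory=lambda: {"air": 10.0, "fat": 100.0,
                                 "dense": 180.0, "muscle": 220.0}
    )
    dense_split: float = 25.0
    noise_sd: float = 4.0
    max_gray: float = 255.0
    muscle_top_col: int | None = None   # MLO; default 0.55 * horizontal axis
    muscle_bottom_row: int | None = None  # MLO; default 0.55 * image height
    blob_region: str = "any"
    seed: int = 0

    def validate(self) -> None:
        lv = self.intensity_levels
        if not (lv["air"] < lv["fat"] < lv["dense"]):
            raise ParameterError("intensity levels must satisfy air < fat < dense")
        if self.view == "MLO" and lv["muscle"] < lv["dense"]:
            raise ParameterError("muscle level must be >= dense on MLO")
        if self.view not in ("CC", "MLO"):
            raise ParameterError(f"view must be CC or MLO, got {self.view!r}")
        if self.laterality not in ("L", "R"):
            raise ParameterError("laterality must be L or R")
        if not 0 < self.nipple_position < 1:
            raise ParameterError("nipple_position must be in (0, 1)")
        if self.blob_region not in ("any", "top", "bottom"):
            raise ParameterError("blob_region must be any|top|bottom")
        if self.n_dense_blobs < 0 or self.noise_sd < 0:
            raise ParameterError("n_dense_blobs and noise_sd must be >= 0")
        if not (0 < self.dense_split + lv["dense"] <= self.max_gray):
            if self.dense_split < 0:
                raise ParameterError("dense_split must be >= 0")
        b, a = self.breast_semi_axes
        H, W = self.image_height, self.image_width
        cy = H / 2.0
        if cy - b < 0 or cy + b > H - 1 or a > W - 1 or a <= 0 or b <= 0:
            raise SizingError(
                f"breast semi-axes {self.breast_semi_axes} do not fit in a "
                f"{H}x{W} frame: the breast must be fully included"
            )


@dataclass
class PhantomGroundTruth:
    """Pre-noise exact masks and landmarks for one phantom.

    ``true_BA``/``true_DA`` are in cm² (pixel count × spacing² / 100).
    ``muscle_mask`` is empty on CC views. ``chest_wall_seed_point`` is the
    operator point P on the breast-muscle interface (MLO; ``None`` on CC).
    """

    breast_mask: np.ndarray
    dense_mask: np.ndarray
    muscle_mask: np.ndarray
    nipple: tuple[int, int]
    chest_wall_seed_point: tuple[int, int] | None
    true_BA: float
    true_DA: float


def _place_blobs(rng, breast: np.ndarray, spec: PhantomSpec
                 ) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping disks fully inside the breast.

    Blobs are drawn sequentially from the RNG stream, so two specs that
    differ only in ``n_dense_blobs`` share their first blobs: increasing the
    count never removes (hence never shrinks) dense area.
    """
    H, W = breast.shape
    rows_ok, cols_ok = np.nonzero(breast)
    if rows_ok.size == 0:
        return []
    cy = H / 2.0
    b = spec.breast_semi_axes[0]
    placed: list[tuple[int, int, int]] = []
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]
    rmin, rmax = spec.blob_radius_range
    for _ in range(spec.n_dense_blobs):
        for _attempt in range(400):
            i = rng.integers(rows_ok.size)
            r0, c0 = int(rows_ok[i]), int(cols_ok[i])
            rad = int(rng.integers(rmin, rmax + 1))
            # 'top'/'bottom' keep the whole disk well inside the superior /
            # inferior half, clear of any plausible nipple bisector
            if spec.blob_region == "top" and r0 + rad > cy - b / 4:
                continue
            if spec.blob_region == "bottom" and r0 - rad < cy + b / 4:
                continue
            disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            if np.any(disk & ~breast):
                continue  # must be fully inside the breast
            # keep disks separated by >= 2 px so edges stay hard
            if any((r0 - r1) ** 2 + (c0 - c1) ** 2 < (rad + rad1 + 2) ** 2
                   for r1, c1, rad1 in placed):
                continue
            placed.append((r0, c0, rad))
            break
    return placed


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[MammogramImage, PhantomGroundTruth]:
    """Generate one phantom view and its exact ground truth.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    images and masks on every call.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    b, a = spec.breast_semi_axes
    cy = H / 2.0
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]

    ellipse = (cc / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0

    muscle = np.zeros((H, W), dtype=bool)
    seed_point = None
    if spec.view == "MLO":
        c_top = spec.muscle_top_col if spec.muscle_top_col is not None \
            else int(round(0.55 * a))
        r_bot = spec.muscle_bottom_row if spec.muscle_bottom_row is not None \
            else int(round(0.55 * H))
        if not (0 < c_top < W and 0 < r_bot < H):
            raise SizingError("muscle wedge outside the image frame")
        cut = c_top * (1.0 - rr / r_bot)  # straight oblique interface
        muscle = ellipse & (cc < cut)
        m_rows = np.nonzero(muscle.any(axis=1))[0]
        if m_rows.size == 0:
            raise SizingError("muscle wedge does not intersect the breast")
        r_p = int(m_rows[m_rows.size // 2])
        c_p = int(round(c_top * (1.0 - r_p / r_bot)))
        seed_point = (r_p, max(c_p, 0))

    breast = ellipse & ~muscle

    # nipple on the anterior contour: angle from superior (-pi/2) to
    # inferior (+pi/2); pulled 1.5 px inward so it lies inside the mask
    phi = (spec.nipple_position - 0.5) * np.pi
    shrink = 1.0 - 1.5 / max(a, b)
    nip = (int(round(cy + b * shrink * np.sin(phi))),
           int(round(a * shrink * np.cos(phi))))

    blobs = _place_blobs(rng, breast, spec)
    dense = np.zeros((H, W), dtype=bool)
    lv = spec.intensity_levels
    img = np.full((H, W), lv["air"], dtype=np.float64)
    img[breast] = lv["fat"]
    if spec.view == "MLO":
        img[muscle] = lv["muscle"]
    for i, (r0, c0, rad) in enumerate(blobs):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        dense |= disk
        level = lv["dense"] + (spec.dense_split if i % 2 else 0.0)
        img[disk] = min(level, spec.max_gray)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, spec.max_gray)

    px = spec.pixel_spacing**2 / 100.0
    truth = PhantomGroundTruth(
        breast_mask=breast,
        dense_mask=dense,
        muscle_mask=muscle,
        nipple=nip,
        chest_wall_seed_point=seed_point,
        true_BA=float(breast.sum()) * px,
        true_DA=float(dense.sum()) * px,
    )
    image = MammogramImage(
        pixels=img,
        view=spec.view,
        laterality=spec.laterality,
        pixel_spacing=spec.pixel_spacing,
        bit_depth=8 if spec.max_gray <= 255 else 16,
    )
    return image, truth
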