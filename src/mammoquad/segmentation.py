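"""Breast foreground and dense-tissue segmentation.

Two FCM stages, following the standard quantitative-density workflow:

1. ``segment_breast`` — FCM with 4 clusters on the whole image; the cluster
   with the lowest centroid is air and defines the anterior breast boundary.
   The breast foreground is everything that is not air, cleaned up to the
   largest connected component with holes filled. On MLO views this
   foreground still contains the pectoral muscle; the geometry module removes
   it using the traced chest-wall boundary.

2. ``classify_tissue`` — FCM with 3 clusters restricted to breast pixels; the
   lowest-centroid cluster is fat, and the two higher clusters together are
   dense (fibroglandular) tissue. Hard assignment is by maximum membership.

Cluster identity is always defined through centroid order, never through the
arbitrary cluster index, so any relabelling of the FCM output leaves the
masks unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, DegenerateInputWarning, InputError
from .fcm import FCMResult, fcm_cluster
from .image import MammogramImage

__all__ = ["TissueSegmentation", "segment_breast", "classify_tissue"]

#: smallest believable breast foreground, as a fraction of the frame
MIN_BREAST_FRACTION = 0.005


@dataclass
class TissueSegmentation:
    """Per-view tissue masks and the FCM diagnostics that produced them.

    ``dense_mask`` and ``fat_mask`` partition ``breast_mask`` exactly.
    ``degenerate`` flags the single-tissue fallback (a breast with fewer than
    three distinct gray values is reported as all fat, no dense pixels).
    """

    breast_mask: np.ndarray
    dense_mask: np.ndarray
    fat_mask: np.ndarray
    inner_fcm: FCMResult | None
    outer_fcm: FCMResult | None = None
    degenerate: bool = False


def segment_breast(
    image: MammogramImage,
    seed: int = 0,
    k: int = 4,
    min_breast_fraction: float = MIN_BREAST_FRACTION,
) -> tuple[np.ndarray, FCMResult]:
    """Separate breast foreground from air.

    Runs FCM with ``k`` clusters (default 4) on all pixels; pixels hard-
    assigned to the lowest-centroid (air) cluster are background. The
    foreground is reduced to its largest connected component and holes are
    filled.

    Returns
    -------
    (mask, fcm_result)
        Boolean foreground mask (breast, plus pectoral muscle on MLO) and
        the outer FCM diagnostics.

    Raises
    ------
    DegenerateInputError
        Near-constant image, or a foreground smaller than
        ``min_breast_fraction`` of the frame (e.g. a few-pixel speck is
        never reported as a breast).
    """
    result = fcm_cluster(image.pixels.ravel(), k=k, seed=seed)
    c = result.centroids
    if (c[1] - c[0]) < 0.05 * (c[-1] - c[0]):
        raise DegenerateInputError(
            "air cluster indistinguishable from tissue: lowest two centroids "
            f"differ by {c[1] - c[0]:.3g} over a {c[-1] - c[0]:.3g} span"
        )
    labels = result.hard_labels.reshape(image.shape)
    foreground = labels != 0  # cluster 0 has the lowest centroid: air

    lab, n = ndimage.label(foreground)
    if n == 0:
        raise DegenerateInputError("no foreground pixels: image is all air")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)

    if mask.sum() < min_breast_fraction * mask.size:
        raise DegenerateInputError(
            f"foreground covers {mask.sum()} px "
            f"(< {min_breast_fraction:.1%} of frame): no plausible breast"
        )
    return mask, result


def classify_tissue(
    image: MammogramImage,
    breast_mask: np.ndarray,
    seed: int = 0,
    k: int = 3,
    outer_fcm: FCMResult | None = None,
) -> TissueSegmentation:
    """Classify breast pixels into fat and dense tissue.

    FCM with ``k`` clusters (default 3) on breast pixels only; the lowest-
    centroid cluster becomes fat and the remaining (higher-centroid) clusters
    together become dense tissue. ``breast_mask`` must already exclude the
    pectoral muscle (see :mod:`mammoquad.geometry` for MLO views).

    A breast with fewer than ``k`` distinct gray values triggers the
    documented single-tissue fallback: a :class:`DegenerateInputWarning` is
    emitted and the segmentation is returned with an empty dense mask and
    ``degenerate=True``.
    """
    breast_mask = np.asarray(breast_mask, bool)
    if breast_mask.shape != image.shape:
        raise InputError("breast_mask shape does not match image")
    if not breast_mask.any():
        raise InputError("breast_mask is empty")

    values = image.pixels[breast_mask]
    if np.unique(values).size < k:
        warnings.warn(
            "breast has fewer distinct gray values than tissue clusters; "
            "single-tissue fallback: no dense pixels reported",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return TissueSegmentation(
            breast_mask=breast_mask,
            dense_mask=np.zeros_like(breast_mask),
            fat_mask=breast_mask.copy(),
            inner_fcm=None,
            outer_fcm=outer_fcm,
            degenerate=True,
        )

    result = fcm_cluster(values, k=k, seed=seed)
    dense_mask = np.zeros_like(breast_mask)
    dense_mask[breast_mask] = result.hard_labels > 0  # clusters above fat
    fat_mask = breast_mask & ~dense_mask
    return TissueSegmentation(
        breast_mask=breast_mask,
        dense_mask=dense_mask,
        fat_mask=fat_mask,
        inner_fcm=result,
        outer_fcm=outer_fcm,
    )
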