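"""Area measurement and quadrant combination.

Areas are pixel counts scaled by the pixel spacing: with spacing in mm/pixel,
``area_cm2 = n_pixels * spacing**2 / 100``. Percent density is
``PD = 100 * DA / BA``.

The four breast quadrants are assembled from the two half-view partitions of
each view: the upper-outer quadrant (UO) combines the CC lateral half with
the MLO superior half, UI combines CC-M with MLO-S, LO combines CC-L with
MLO-I, and LI combines CC-M with MLO-I. Because the breast is imaged (and
therefore counted) once per view, the default combination is

    Q = (CC_half + MLO_half) / 4

i.e. the average of the two contributing halves, halved again to undo the
double counting. Under this rule the four quadrant areas sum exactly to the
mean of the two single-view breast areas, so quadrant BAs add up to the
whole-breast BA. A ``half_sum`` mode (``(CC + MLO) / 2``) is provided for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "QUADRANTS",
    "PartitionMeasurement",
    "QuadrantProfile",
    "measure_partition",
    "combine_quadrants",
]

QUADRANTS = ("UO", "UI", "LO", "LI")
PARTITION_LABELS = ("CC-L", "CC-M", "MLO-S", "MLO-I")

#: quadrant -> (CC half, MLO half) it combines
QUADRANT_PARTS = {
    "UO": ("CC-L", "MLO-S"),
    "UI": ("CC-M", "MLO-S"),
    "LO": ("CC-L", "MLO-I"),
    "LI": ("CC-M", "MLO-I"),
}


@dataclass
class PartitionMeasurement:
    """Breast area and dense area (cm²) of one half-view partition."""

    label: str
    BA: float
    DA: float

    def __post_init__(self) -> None:
        if self.label not in PARTITION_LABELS:
            raise InputError(f"unknown partition label {self.label!r}")
        if not (0 <= self.DA <= self.BA + 1e-12):
            raise InputError(
                f"{self.label}: DA={self.DA} outside [0, BA={self.BA}]"
            )


@dataclass
class QuadrantProfile:
    """BA, DA (cm²) and PD (%) for the four quadrants and the whole breast.

    ``pd[q]`` is NaN where ``ba[q]`` is zero; such quadrants are listed in
    ``undefined_pd`` and excluded from rank analyses downstream.
    """

    ba: dict[str, float]
    da: dict[str, float]
    pd: dict[str, float] = field(default_factory=dict)
    whole_ba: float = 0.0
    whole_da: float = 0.0
    whole_pd: float = float("nan")
    undefined_pd: tuple[str, ...] = ()

    @classmethod
    def from_areas(cls, ba: dict[str, float], da: dict[str, float]
                   ) -> "QuadrantProfile":
        """Build a profile from per-quadrant areas; PD and whole-breast
        totals are derived."""
        missing = [q for q in QUADRANTS if q not in ba or q not in da]
        if missing:
            raise InputError(f"missing quadrants: {missing}")
        pd = {}
        undefined = []
        for q in QUADRANTS:
            if not (0 <= da[q] <= ba[q] + 1e-12):
                raise InputError(f"{q}: DA={da[q]} outside [0, BA={ba[q]}]")
            if ba[q] > 0:
                pd[q] = 100.0 * da[q] / ba[q]
            else:
                pd[q] = float("nan")
                undefined.append(q)
        whole_ba = float(sum(ba[q] for q in QUADRANTS))
        whole_da = float(sum(da[q] for q in QUADRANTS))
        whole_pd = 100.0 * whole_da / whole_ba if whole_ba > 0 else float("nan")
        return cls(
            ba={q: float(ba[q]) for q in QUADRANTS},
            da={q: float(da[q]) for q in QUADRANTS},
            pd=pd,
            whole_ba=whole_ba,
            whole_da=whole_da,
            whole_pd=whole_pd,
            undefined_pd=tuple(undefined),
        )

    def values(self, statistic: str) -> dict[str, float]:
        """Per-quadrant values of ``'BA'``, ``'DA'`` or ``'PD'``."""
        stat = statistic.upper()
        if stat == "BA":
            return dict(self.ba)
        if stat == "DA":
            return dict(self.da)
        if stat == "PD":
            return dict(self.pd)
        raise ParameterError(f"unknown statistic {statistic!r}")


def measure_partition(
    breast_mask: np.ndarray,
    dense_mask: np.ndarray,
    partition_mask: np.ndarray,
    pixel_spacing: float,
    label: str = "CC-L",
) -> PartitionMeasurement:
    """Measure BA and DA (cm²) of one half-view partition.

    An empty partition yields BA = 0 with a warning (PD is undefined
    downstream).
    """
    if not pixel_spacing > 0:
        raise ParameterError("pixel_spacing must be > 0")
    breast = np.asarray(breast_mask, bool)
    dense = np.asarray(dense_mask, bool)
    part = np.asarray(partition_mask, bool)
    if breast.shape != dense.shape or breast.shape != part.shape:
        raise InputError("mask shapes differ")
    if np.any(dense & ~breast):
        raise InputError("dense_mask is not a subset of breast_mask")

    px_area = pixel_spacing**2 / 100.0  # mm² -> cm²
    ba = float(np.count_nonzero(breast & part)) * px_area
    da = float(np.count_nonzero(dense & part)) * px_area
    if ba == 0.0:
        warnings.warn(f"partition {label} contains no breast pixels; BA = 0",
                      UserWarning, stacklevel=2)
    return PartitionMeasurement(label=label, BA=ba, DA=da)


def combine_quadrants(
    cc: dict[str, PartitionMeasurement] | list[PartitionMeasurement],
    mlo: dict[str, PartitionMeasurement] | list[PartitionMeasurement],
    mode: str = "quarter_sum",
) -> QuadrantProfile:
    """Combine CC and MLO half-view measurements into quadrant BA/DA/PD.

    ``mode='quarter_sum'`` (default): Q = (CC_half + MLO_half) / 4, so the
    quadrants sum to the mean of the two single-view totals.
    ``mode='half_sum'``: Q = (CC_half + MLO_half) / 2.
    """
    if mode not in ("quarter_sum", "half_sum"):
        raise ParameterError(f"unknown combination mode {mode!r}")
    div = 4.0 if mode == "quarter_sum" else 2.0

    def _as_map(parts, wanted):
        if not isinstance(parts, dict):
            parts = {p.label: p for p in parts}
        missing = [w for w in wanted if w not in parts]
        if missing:
            raise InputError(f"missing partitions: {missing}")
        return parts

    cc = _as_map(cc, ("CC-L", "CC-M"))
    mlo = _as_map(mlo, ("MLO-S", "MLO-I"))
    parts = {**cc, **mlo}
    ba = {}
    da = {}
    for q, (p_cc, p_mlo) in QUADRANT_PARTS.items():
        ba[q] = (parts[p_cc].BA + parts[p_mlo].BA) / div
        da[q] = (parts[p_cc].DA + parts[p_mlo].DA) / div
    return QuadrantProfile.from_areas(ba, da)
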