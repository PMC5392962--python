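"""End-to-end orchestration: images -> segmentation -> geometry -> quadrant
profiles -> cohort tables.

Two entry modes:

* **image mode** — :func:`run_single_breast` runs the full imaging chain on a
  CC/MLO pair (with nipple and chest-wall-seed landmarks) and returns the
  breast's :class:`~mammoquad.density.QuadrantProfile`;
  :func:`run_cohort_images` maps it over a manifest table, keeping an
  exclusion record per failed row.
* **table mode** — :func:`run_cohort_table` starts from a per-woman quadrant
  CSV (as produced by the cohort generator or a previous image-mode run) and
  computes the statistics tables only. Reproducing printed cohort tables
  from counts is only possible in this mode, since the source mammograms are
  not public.

All runs are deterministic given the configuration seed, and every output
CSV ends with a config-hash provenance comment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import CohortRecord, cohort_from_dataframe
from .config import RunConfig
from .density import QuadrantProfile, combine_quadrants, measure_partition
from .errors import MammoquadError, InputError
from .geometry import bisect_cc, bisect_mlo, exclude_muscle, trace_chest_wall
from .image import MammogramImage
from .report import build_all_tables
from .segmentation import classify_tissue, segment_breast

__all__ = ["StageError", "run_single_breast", "run_cohort_table",
           "run_cohort_images", "write_tables"]

log = logging.getLogger("mammoquad")


class StageError(MammoquadError):
    """A pipeline stage failed; carries the stage name and image id."""

    def __init__(self, stage: str, image_id: str, cause: Exception):
        super().__init__(f"[{stage}] {image_id}: {cause}")
        self.stage = stage
        self.image_id = image_id
        self.cause = cause


@dataclass
class Landmarks:
    """Manual landmarks for one breast's view pair (pixel coordinates)."""

    cc_nipple: tuple[float, float]
    mlo_nipple: tuple[float, float]
    mlo_chest_seed: tuple[int, int]


def _normalize(image: MammogramImage) -> MammogramImage:
    px = image.pixels
    rng = px.max() - px.min()
    if rng == 0:
        return image
    return MammogramImage(pixels=(px - px.min()) / rng,
                          view=image.view, laterality=image.laterality,
                          pixel_spacing=image.pixel_spacing,
                          bit_depth=image.bit_depth)


def run_single_breast(
    cc_image: MammogramImage,
    mlo_image: MammogramImage,
    landmarks: Landmarks,
    config: RunConfig | None = None,
    image_id: str = "breast",
) -> QuadrantProfile:
    """Full imaging chain for one breast (CC + MLO pair).

    Both views must share laterality. Stage failures re-raise as
    :class:`StageError` naming the stage and image id.
    """
    config = config or RunConfig()
    config.validate()
    if cc_image.view != "CC" or mlo_image.view != "MLO":
        raise InputError("expected a CC image and an MLO image, in that order")
    if cc_image.laterality != mlo_image.laterality:
        raise InputError("CC and MLO views have different laterality")
    if config.normalize_intensities:
        cc_image, mlo_image = _normalize(cc_image), _normalize(mlo_image)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, image_id, exc) from exc

    # --- CC chain: no muscle on CC, the image edge is the chest wall
    cc_mask, cc_outer = _stage(
        "segment_breast/CC", segment_breast, cc_image,
        seed=config.seed, k=config.clusters_outer)
    cc_seg = _stage(
        "classify_tissue/CC", classify_tissue, cc_image, cc_mask,
        seed=config.seed, k=config.clusters_inner, outer_fcm=cc_outer)
    cc_part = _stage(
        "bisect_cc", bisect_cc, cc_mask, landmarks.cc_nipple,
        cc_image.laterality)
    cc_meas = {
        lbl: measure_partition(cc_seg.breast_mask, cc_seg.dense_mask,
                               m, cc_image.pixel_spacing, label=lbl)
        for lbl, m in cc_part.masks.items()
    }

    # --- MLO chain: trace chest wall, exclude muscle, then classify
    mlo_fg, mlo_outer = _stage(
        "segment_breast/MLO", segment_breast, mlo_image,
        seed=config.seed, k=config.clusters_outer)
    boundary = _stage(
        "trace_chest_wall", trace_chest_wall, mlo_image,
        landmarks.mlo_chest_seed, window=config.trace_window)
    mlo_mask = exclude_muscle(mlo_fg, boundary)
    mlo_seg = _stage(
        "classify_tissue/MLO", classify_tissue, mlo_image, mlo_mask,
        seed=config.seed, k=config.clusters_inner, outer_fcm=mlo_outer)
    mlo_part = _stage(
        "bisect_mlo", bisect_mlo, mlo_mask, landmarks.mlo_nipple, boundary)
    mlo_meas = {
        lbl: measure_partition(mlo_seg.breast_mask, mlo_seg.dense_mask,
                               m, mlo_image.pixel_spacing, label=lbl)
        for lbl, m in mlo_part.masks.items()
    }

    profile = combine_quadrants(cc_meas, mlo_meas, mode=config.combination_mode)
    log.info("%s: whole-breast BA=%.1f cm² DA=%.1f cm² PD=%.1f%%",
             image_id, profile.whole_ba, profile.whole_da, profile.whole_pd)
    return profile


def run_cohort_table(cohort_csv: str | Path | pd.DataFrame,
                     config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Statistics-only run from a per-woman quadrant table."""
    config = config or RunConfig()
    config.validate()
    df = cohort_csv if isinstance(cohort_csv, pd.DataFrame) \
        else pd.read_csv(cohort_csv, comment="#")
    if df.empty:
        log.warning("zero women in cohort table: emitting empty tables")
        return {name: pd.DataFrame() for name in
                ("table1", "table2", "table3", "table4_DA", "table4_PD",
                 "odds", "symmetry")}
    records = cohort_from_dataframe(df)
    return build_all_tables(records)


def run_cohort_images(
    manifest: str | Path | pd.DataFrame,
    image_root: str | Path = ".",
    config: RunConfig | None = None,
) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Image-mode cohort run over a manifest table.

    Manifest columns: ``woman_id, tumor_quadrant, cc_image, mlo_image,
    cc_nipple_row, cc_nipple_col, mlo_nipple_row, mlo_nipple_col,
    seed_row, seed_col``. Malformed or failing rows are listed in the
    returned exclusions frame and the run continues; processed + excluded
    always equals the number of manifest rows.
    """
    config = config or RunConfig()
    config.validate()
    df = manifest if isinstance(manifest, pd.DataFrame) \
        else pd.read_csv(manifest, comment="#")
    root = Path(image_root)
    records: list[CohortRecord] = []
    exclusions = []
    required = ["woman_id", "tumor_quadrant", "cc_image", "mlo_image",
                "cc_nipple_row", "cc_nipple_col", "mlo_nipple_row",
                "mlo_nipple_col", "seed_row", "seed_col"]
    for i, row in df.iterrows():
        wid = str(row.get("woman_id", f"row{i}"))
        try:
            missing = [c for c in required
                       if c not in row or pd.isna(row[c])]
            if missing:
                raise InputError(f"missing manifest fields {missing}")
            cc = MammogramImage.load(root / str(row["cc_image"]))
            mlo = MammogramImage.load(root / str(row["mlo_image"]))
            lm = Landmarks(
                cc_nipple=(float(row["cc_nipple_row"]),
                           float(row["cc_nipple_col"])),
                mlo_nipple=(float(row["mlo_nipple_row"]),
                            float(row["mlo_nipple_col"])),
                mlo_chest_seed=(int(row["seed_row"]), int(row["seed_col"])),
            )
            profile = run_single_breast(cc, mlo, lm, config, image_id=wid)
            records.append(CohortRecord(
                woman_id=wid, tumor_quadrant=str(row["tumor_quadrant"]),
                normal_breast=profile))
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            exclusions.append({"woman_id": wid, "reason": str(exc)})
            log.warning("excluded %s: %s", wid, exc)
    excl = pd.DataFrame(exclusions, columns=["woman_id", "reason"])
    log.info("processed %d, excluded %d of %d manifest rows",
             len(records), len(excl), len(df))
    return records, excl


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path,
                 config: RunConfig | None = None) -> list[Path]:
    """Write each table as CSV into ``outdir``, appending a provenance
    comment with the config hash."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            frame.to_csv(fh, index=isinstance(frame.index, pd.Index)
                         and frame.index.name is not None
                         or not frame.index.equals(pd.RangeIndex(len(frame))))
            fh.write(f"# config_hash={config.hash}\n")
        written.append(path)
    return written
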