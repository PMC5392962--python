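"""Cohort report tables.

Builders for the standard result tables of a quadrant-density study:

* table 1 — mean ± SD of BA, DA, PD per quadrant and whole breast;
* table 2 — the same, stratified by tumor group;
* table 3 — per-quadrant counts of tumor location, highest DA, highest PD,
  and tumor-in-highest tallies;
* table 4 — tumor group × rank cross-tabulations for DA and PD;
* odds — per-quadrant odds of tumor location with 95% limits;
* symmetry — pooled bilateral Pearson correlation of PD.

Values are carried at full precision; display rounding (odds and CIs to two
decimals, percentages to one, BA to whole cm², DA to one decimal) happens
only in the formatted ``*_display`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .density import QUADRANTS
from . import stats as mstats

__all__ = ["table1", "table2", "table3", "table4", "odds_table",
           "symmetry_table", "build_all_tables"]

_ROWS = list(QUADRANTS) + ["Whole"]


def _mean_sd_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for label in _ROWS:
        row = {"quadrant": label}
        for v in ("BA", "DA", "PD"):
            if label == "Whole":
                vals = np.array([
                    {"BA": r.normal_breast.whole_ba,
                     "DA": r.normal_breast.whole_da,
                     "PD": r.normal_breast.whole_pd}[v]
                    for r in records])
            else:
                vals = np.array([r.normal_breast.values(v)[label]
                                 for r in records])
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean()) if vals.size else np.nan
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            row[f"{v}_mean"], row[f"{v}_sd"] = mean, sd
            fmt = {"BA": "{:.0f} ± {:.0f}", "DA": "{:.1f} ± {:.1f}",
                   "PD": "{:.1f} ± {:.1f}"}[v]
            row[f"{v}_display"] = (fmt.format(mean, sd)
                                   if np.isfinite(mean) else "")
        rows.append(row)
    return pd.DataFrame(rows)


def table1(records: list[CohortRecord]) -> pd.DataFrame:
    """Normal-breast BA/DA/PD per quadrant and whole breast, mean ± SD."""
    return _mean_sd_frame(records)


def table2(records: list[CohortRecord]) -> pd.DataFrame:
    """Per-tumor-group quadrant means ± SD (long format, one row per
    group × quadrant)."""
    frames = []
    for g in QUADRANTS:
        sub = [r for r in records if r.tumor_quadrant == g]
        if not sub:
            continue
        f = _mean_sd_frame(sub)
        f.insert(0, "tumor_group", g)
        f.insert(1, "n", len(sub))
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def table3(records: list[CohortRecord]) -> pd.DataFrame:
    """Counts (and percentages of N) of tumor location, highest DA and
    highest PD per quadrant, plus tumor-in-highest tallies."""
    tab = mstats.highest_quadrant_summary(records)
    n = len(records)
    out = tab.astype(object)
    for row in ("tumor_location", "highest_DA", "highest_PD"):
        for q in QUADRANTS:
            c = int(tab.loc[row, q])
            out.loc[row + "_display", q] = f"{c} ({100.0 * c / n:.1f}%)" \
                if n else str(c)
    return out


def table4(records: list[CohortRecord]) -> dict[str, pd.DataFrame]:
    """Rank cross-tabs for DA and PD, as ``{'DA': frame, 'PD': frame}``
    with count and per-group percentage columns."""
    out = {}
    for stat in ("DA", "PD"):
        ct = mstats.build_rank_crosstab(records, stat)
        frame = ct.to_dataframe()
        for r in range(4):
            frame[f"rank_{r + 1}_pct"] = 100.0 * ct.row_proportions[:, r]
        frame.insert(0, "n", ct.counts.sum(axis=1))
        out[stat] = frame
    return out


def odds_table(records: list[CohortRecord] | None = None,
               counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-quadrant odds of tumor location with 95% limits.

    Accepts either a cohort or explicit per-quadrant counts.
    """
    if counts is None:
        if records is None:
            raise ValueError("provide records or counts")
        counts = {q: sum(r.tumor_quadrant == q for r in records)
                  for q in QUADRANTS}
    N = sum(counts.values())
    rows = []
    for q in QUADRANTS:
        est = mstats.quadrant_odds(counts[q], N, quadrant=q)
        rows.append({
            "quadrant": q, "n_tumors": est.n_tumors, "n_total": est.n_total,
            "odds": est.odds, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "display": f"{est.odds:.2f} ({est.ci_low:.2f}, {est.ci_high:.2f})",
        })
    return pd.DataFrame(rows)


def symmetry_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Bilateral PD symmetry (pooled non-tumor quadrants), one-row frame."""
    res = mstats.bilateral_symmetry(records)
    return pd.DataFrame([res])


def build_all_tables(records: list[CohortRecord]) -> dict[str, pd.DataFrame]:
    """All report tables keyed by name (table4 split into DA/PD)."""
    t4 = table4(records)
    tables = {
        "table1": table1(records),
        "table2": table2(records),
        "table3": table3(records),
        "table4_DA": t4["DA"],
        "table4_PD": t4["PD"],
        "odds": odds_table(records),
    }
    try:
        tables["symmetry"] = symmetry_table(records)
    except Exception:  # no diseased-breast profiles in image-mode runs
        tables["symmetry"] = pd.DataFrame()
    return tables
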