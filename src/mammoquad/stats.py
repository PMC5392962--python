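"""Cohort statistics: odds of tumor location, rank analyses, symmetry.

Odds of tumor development in a quadrant are ``n / (N - n)`` with a Wald 95%
interval on the log-odds scale,

    exp( log(n/(N-n)) +- z * sqrt(1/n + 1/(N-n)) ),  z = 1.96.

Equality of the four location probabilities is tested with a chi-square
score test against H0: p = 1/4 each (df = 3); because every woman
contributes exactly one tumor quadrant, the repeated-measures formulation
reduces to this multinomial test. Pairwise quadrant comparisons condition on
the two counts involved (binomial z on n_i vs n_j given n_i + n_j) and are
Bonferroni-adjusted.

Rank analyses use dense ranking (1 = highest) of a woman's four quadrant
values, with ties broken by the fixed quadrant order UO, UI, LO, LI.
Bilateral symmetry pools, per woman, the percent densities of the three
non-tumor quadrants of the diseased breast against the same quadrants of
the contralateral normal breast, and reports the Pearson correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import CohortRecord
from .density import QUADRANTS, QuadrantProfile
from .errors import InputError, ParameterError

__all__ = [
    "OddsEstimate",
    "RankCrossTab",
    "quadrant_odds",
    "proportions_difference_test",
    "rank_quadrants",
    "build_rank_crosstab",
    "highest_quadrant_summary",
    "bilateral_symmetry",
    "quadrant_comparison_tests",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class OddsEstimate:
    """Odds of tumor occurrence in one quadrant with 95% Wald limits."""

    quadrant: str
    n_tumors: int
    n_total: int
    odds: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


@dataclass
class RankCrossTab:
    """Tumor group x rank cross-tabulation for DA or PD.

    ``counts[g, r]`` is the number of women with tumor in quadrant
    ``QUADRANTS[g]`` whose tumor-quadrant statistic ranks ``r + 1`` among
    her four quadrants. ``row_proportions`` are counts normalised per group
    (NaN for empty groups). ``n_excluded`` counts women dropped because the
    statistic was undefined (BA = 0) in some quadrant.
    """

    statistic: str
    counts: np.ndarray
    row_proportions: np.ndarray
    n_excluded: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"{q} tumor" for q in QUADRANTS],
            columns=[f"rank_{r}" for r in (1, 2, 3, 4)],
        )


def quadrant_odds(n_q: int, N: int, quadrant: str = "UO",
                  z: float = Z_95) -> OddsEstimate:
    """Odds ``n/(N-n)`` of tumor location in a quadrant, with 95% limits.

    Boundary counts (``n_q`` of 0 or N) have infinite or zero odds; the
    interval then falls back to a +0.5 continuity correction on both counts
    and the estimate is flagged ``continuity_corrected``.
    """
    if N <= 0 or not 0 <= n_q <= N:
        raise InputError(f"need 0 <= n_q <= N with N > 0, got n_q={n_q}, N={N}")
    n, m = float(n_q), float(N - n_q)
    corrected = False
    if n == 0 or m == 0:
        warnings.warn(
            f"boundary count n={n_q}/{N}: odds degenerate, CI uses +0.5 "
            "continuity correction", UserWarning, stacklevel=2)
        n, m = n + 0.5, m + 0.5
        corrected = True
    odds = n / m
    se = math.sqrt(1.0 / n + 1.0 / m)
    lo = math.exp(math.log(odds) - z * se)
    hi = math.exp(math.log(odds) + z * se)
    point = (float(n_q) / (N - n_q)) if 0 < n_q < N else (
        0.0 if n_q == 0 else math.inf)
    return OddsEstimate(quadrant=quadrant, n_tumors=n_q, n_total=N,
                        odds=point if not corrected else odds,
                        ci_low=lo, ci_high=hi,
                        continuity_corrected=corrected)


def proportions_difference_test(counts) -> dict:
    """Score-type test of equal tumor-location probabilities across the four
    quadrants, plus Bonferroni-adjusted pairwise comparisons.

    Returns a dict with ``statistic`` (chi-square, df = 3), ``p_value`` and a
    ``pairwise`` DataFrame (conditional binomial z per quadrant pair with
    raw and adjusted p-values).
    """
    counts = np.asarray(counts, float)
    if counts.size != 4 or np.any(counts < 0):
        raise InputError("counts must be 4 non-negative tumor counts")
    total = counts.sum()
    if total == 0:
        raise InputError("total count is zero")
    expected = np.full(4, total / 4.0)
    stat, p = sps.chisquare(counts, expected)

    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            ni, nj = counts[i], counts[j]
            if ni + nj == 0:
                zstat, praw = 0.0, 1.0
            else:
                # conditional on n_i + n_j, n_i ~ Binomial(n_i+n_j, 1/2)
                zstat = (ni - nj) / math.sqrt(ni + nj)
                praw = 2.0 * sps.norm.sf(abs(zstat))
            rows.append({"pair": f"{QUADRANTS[i]} vs {QUADRANTS[j]}",
                         "z": zstat, "p_raw": min(praw, 1.0)})
    pair = pd.DataFrame(rows)
    pair["p_adj"] = multipletests(pair["p_raw"], method="bonferroni")[1]
    return {"statistic": float(stat), "df": 3, "p_value": float(p),
            "pairwise": pair}


def rank_quadrants(profile: QuadrantProfile, statistic: str) -> dict[str, int]:
    """Dense descending ranks (1 = highest) of a breast's four quadrant
    values; ties broken by the fixed quadrant order UO, UI, LO, LI.

    Raises :class:`InputError` when the statistic is undefined (NaN) in any
    quadrant; callers exclude such women with a logged reason.
    """
    vals = profile.values(statistic)
    if any(not np.isfinite(vals[q]) for q in QUADRANTS):
        bad = [q for q in QUADRANTS if not np.isfinite(vals[q])]
        raise InputError(
            f"{statistic} undefined in quadrant(s) {bad}; woman excluded "
            "from rank analysis"
        )
    order = sorted(QUADRANTS, key=lambda q: (-vals[q], QUADRANTS.index(q)))
    return {q: order.index(q) + 1 for q in QUADRANTS}


def build_rank_crosstab(cohort: list[CohortRecord], statistic: str
                        ) -> RankCrossTab:
    """Cross-tabulate tumor group against the rank of the tumor quadrant's
    DA or PD in the woman's normal breast."""
    counts = np.zeros((4, 4), dtype=int)
    excluded = 0
    for rec in cohort:
        try:
            ranks = rank_quadrants(rec.normal_breast, statistic)
        except InputError:
            excluded += 1
            continue
        g = QUADRANTS.index(rec.tumor_quadrant)
        counts[g, ranks[rec.tumor_quadrant] - 1] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(row_sums > 0, counts / row_sums, np.nan)
    if np.any(row_sums == 0):
        warnings.warn("empty tumor group(s): row proportions undefined",
                      UserWarning, stacklevel=2)
    return RankCrossTab(statistic=statistic.upper(), counts=counts,
                        row_proportions=props, n_excluded=excluded)


def highest_quadrant_summary(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Per-quadrant tallies: tumor location, highest DA, highest PD, and
    tumor-in-highest-DA / tumor-in-highest-PD counts.

    Rows: ``tumor_location``, ``highest_DA``, ``highest_PD``,
    ``tumor_in_highest_DA``, ``tumor_in_highest_PD``; columns UO, UI, LO, LI.
    """
    idx = ["tumor_location", "highest_DA", "highest_PD",
           "tumor_in_highest_DA", "tumor_in_highest_PD"]
    tab = pd.DataFrame(0, index=idx, columns=list(QUADRANTS))
    for rec in cohort:
        tq = rec.tumor_quadrant
        tab.loc["tumor_location", tq] += 1
        for stat, row_high, row_hit in (
            ("DA", "highest_DA", "tumor_in_highest_DA"),
            ("PD", "highest_PD", "tumor_in_highest_PD"),
        ):
            try:
                ranks = rank_quadrants(rec.normal_breast, stat)
            except InputError:
                continue
            top = next(q for q in QUADRANTS if ranks[q] == 1)
            tab.loc[row_high, top] += 1
            if ranks[tq] == 1:
                tab.loc[row_hit, tq] += 1
    return tab


def bilateral_symmetry(cohort: list[CohortRecord]) -> dict:
    """Pearson correlation of diseased- vs normal-breast PD over the three
    non-tumor quadrants of each woman.

    Returns ``{"r", "p_value", "n_pairs", "n_women"}``. Women without a
    diseased-breast profile are skipped; fewer than 3 pooled pairs or zero
    variance raise :class:`InputError`.
    """
    xs, ys = [], []
    n_women = 0
    for rec in cohort:
        if rec.diseased_breast is None:
            continue
        n_women += 1
        for q in QUADRANTS:
            if q == rec.tumor_quadrant:
                continue
            x = rec.diseased_breast.pd[q]
            y = rec.normal_breast.pd[q]
            if np.isfinite(x) and np.isfinite(y):
                xs.append(x)
                ys.append(y)
    if len(xs) < 3:
        raise InputError(f"need >= 3 PD pairs, got {len(xs)}")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if xs.std() == 0 or ys.std() == 0:
        raise InputError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xs, ys)
    return {"r": float(r), "p_value": float(p), "n_pairs": len(xs),
            "n_women": n_women}


def quadrant_comparison_tests(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Paired t-tests between quadrants (within women) and unpaired t-tests
    between tumor groups, for BA, DA and PD of the normal breast.

    Returns a tidy frame with columns ``kind`` (``paired`` or ``group``),
    ``variable``, ``comparison``, ``quadrant`` (group tests only), ``t``,
    ``p_value`` and ``skipped`` (degenerate variance). P-values are
    two-sided and unadjusted.
    """
    if len(cohort) < 2:
        raise InputError("need at least 2 women")
    data = {v: {q: np.array([rec.normal_breast.values(v)[q]
                             for rec in cohort]) for q in QUADRANTS}
            for v in ("BA", "DA", "PD")}
    groups = {q: [i for i, rec in enumerate(cohort)
                  if rec.tumor_quadrant == q] for q in QUADRANTS}

    rows = []
    pairs = [(a, b) for i, a in enumerate(QUADRANTS)
             for b in QUADRANTS[i + 1:]]
    for v in ("BA", "DA", "PD"):
        for a, b in pairs:
            x, y = data[v][a], data[v][b]
            ok = np.isfinite(x) & np.isfinite(y)
            d = x[ok] - y[ok]
            if d.size < 2:
                t, p, skip = np.nan, np.nan, True
            elif np.all(d == d[0]):  # zero variance of the differences
                # identical samples: t = 0, p = 1; a constant non-zero
                # shift has no finite t and is skipped with a flag
                t, p, skip = (0.0, 1.0, False) if d[0] == 0 else (
                    np.nan, np.nan, True)
            else:
                t, p = sps.ttest_rel(x[ok], y[ok])
                skip = False
            rows.append({"kind": "paired", "variable": v,
                         "comparison": f"{a} vs {b}", "quadrant": "",
                         "t": float(t), "p_value": float(p), "skipped": skip})
    for v in ("BA", "DA", "PD"):
        for q in QUADRANTS:
            for a, b in pairs:
                xa = data[v][q][groups[a]]
                xb = data[v][q][groups[b]]
                xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
                if xa.size < 2 or xb.size < 2 or (xa.std() == 0
                                                  and xb.std() == 0):
                    rows.append({"kind": "group", "variable": v,
                                 "comparison": f"{a} vs {b}", "quadrant": q,
                                 "t": np.nan, "p_value": np.nan,
                                 "skipped": True})
                    continue
                t, p = sps.ttest_ind(xa, xb)
                rows.append({"kind": "group", "variable": v,
                             "comparison": f"{a} vs {b}", "quadrant": q,
                             "t": float(t), "p_value": float(p),
                             "skipped": False})
    return pd.DataFrame(rows)
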