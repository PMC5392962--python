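"""Synthetic cohorts with the dependence structure the analysis assumes.

Each woman has a tumor quadrant drawn from a multinomial over (UO, UI, LO,
LI) and, for each breast, per-quadrant breast area (BA) and percent density
(PD). Dense area is derived as ``DA = PD * BA / 100``.

Correlation structure
---------------------
Quadrant values are correlated both *within* a breast (a large or dense
breast is large or dense everywhere) and *between* the two breasts
(bilateral symmetry). Both are modelled with a Kronecker-structured Gaussian
copula: the 8-vector (4 quadrants x 2 sides) of z-scores has correlation

    Sigma = A (x) B,   A = [[1, rho_bilateral], [rho_bilateral, 1]],
                       B[i, j] = rho_intra  (i != j),  B[i, i] = 1,

scaled by the per-quadrant SDs and shifted by the per-quadrant means. The
default intra-breast correlations are derived from the identity relating the
whole-breast SD to the quadrant SDs under this model (whole-breast values
are quadrant sums): for BA, whole-SD 46 cm² against quadrant SDs
(15, 14, 10, 9) gives rho_intra = 0.89; the analogous dense-area identity
gives 0.76, which is also used for PD whose intra correlation is not
separately identifiable from marginal summaries.

Within each (quadrant, side), PD is negatively correlated with BA
(``pd_ba_correlation``, default -0.40): percent density falls with breast
size. The default is the value for which the product DA = PD*BA/100
reproduces the observed quadrant DA standard deviations from the BA and PD
marginals (product-variance identity); it simultaneously recovers the
observed DA means through the mean-of-product correction
``E[DA] = (mu_PD*mu_BA + rho*sigma_PD*sigma_BA) / 100``.

Out-of-range draws (BA <= 0, PD outside [0, 100]) are rejected and the
woman's whole draw redrawn, so truncation introduces no boundary atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import QUADRANTS, QuadrantProfile
from .errors import InputError, ParameterError

__all__ = ["CohortSpec", "CohortRecord", "generate_cohort",
           "cohort_to_dataframe", "cohort_from_dataframe",
           "write_cohort_csv", "read_cohort_csv"]

#: Per-quadrant defaults: normal-breast means/SDs of BA (cm²) and PD (%)
#: for (UO, UI, LO, LI), and the observed tumor-location proportions at
#: N = 110 (67, 16, 7, 20).
DEFAULT_BA_MEANS = (37.0, 34.0, 24.0, 21.0)
DEFAULT_BA_SDS = (15.0, 14.0, 10.0, 9.0)
DEFAULT_PD_MEANS = (20.0, 18.5, 22.8, 20.5)
DEFAULT_PD_SDS = (5.8, 5.2, 7.5, 7.3)
DEFAULT_TUMOR_PROBS = (67 / 110, 16 / 110, 7 / 110, 20 / 110)


@dataclass
class CohortSpec:
    """Distributional parameters of a synthetic cohort."""

    n_women: int = 110
    tumor_probs: tuple[float, float, float, float] = DEFAULT_TUMOR_PROBS
    quadrant_BA_means: tuple = DEFAULT_BA_MEANS
    quadrant_BA_sds: tuple = DEFAULT_BA_SDS
    quadrant_PD_means: tuple = DEFAULT_PD_MEANS
    quadrant_PD_sds: tuple = DEFAULT_PD_SDS
    bilateral_correlation: float = 0.90
    intra_breast_correlation_BA: float = 0.89
    intra_breast_correlation_PD: float = 0.76
    pd_ba_correlation: float = -0.40
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.tumor_probs, float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("tumor_probs must be 4 probabilities summing to 1")
        for sds in (self.quadrant_BA_sds, self.quadrant_PD_sds):
            if len(sds) != 4 or any(s <= 0 for s in sds):
                raise ParameterError("all quadrant SDs must be > 0")
        for rho in (self.bilateral_correlation,
                    self.intra_breast_correlation_BA,
                    self.intra_breast_correlation_PD,
                    self.pd_ba_correlation):
            if not -1.0 <= rho <= 1.0:
                raise ParameterError(f"correlation {rho} outside [-1, 1]")
        r2 = self.pd_ba_correlation**2
        if r2 < 1.0:
            resid = (self.intra_breast_correlation_PD
                     - r2 * self.intra_breast_correlation_BA) / (1.0 - r2)
            if not -1.0 / 3.0 <= resid <= 1.0:
                raise ParameterError(
                    "incompatible intra-breast and PD-BA correlations: "
                    "residual PD correlation matrix is not positive "
                    "semi-definite"
                )
        if self.n_women < 1:
            raise ParameterError("n_women must be >= 1")


@dataclass
class CohortRecord:
    """One woman: tumor quadrant plus both breasts' quadrant profiles.

    ``normal_breast`` is the contralateral (tumor-free) breast used for the
    density analyses; ``diseased_breast`` carries the tumor and is used only
    for the bilateral-symmetry comparison (tumor quadrant excluded there).
    """

    woman_id: str
    tumor_quadrant: str
    normal_breast: QuadrantProfile
    diseased_breast: QuadrantProfile | None = None
    diseased_side: str = "L"

    def __post_init__(self) -> None:
        if self.tumor_quadrant not in QUADRANTS:
            raise InputError(
                f"tumor_quadrant must be one of {QUADRANTS}, "
                f"got {self.tumor_quadrant!r}"
            )


def _sqrt_psd(corr: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root, tolerant of singular correlation
    matrices (e.g. a bilateral correlation of exactly 1)."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def _kron_root(rho_bilateral: float, rho_intra: float) -> np.ndarray:
    """Square root of the Kronecker correlation kron(A, B) as
    kron(sqrt(A), sqrt(B)); at a bilateral correlation of exactly 1 the two
    sides' rows are identical, so the drawn left/right values agree
    bitwise."""
    A = np.array([[1.0, rho_bilateral], [rho_bilateral, 1.0]])
    B = np.full((4, 4), rho_intra)
    np.fill_diagonal(B, 1.0)
    return np.kron(_sqrt_psd(A), _sqrt_psd(B))


def _draw_ba_pd(rng, n, spec: "CohortSpec") -> tuple[np.ndarray, np.ndarray]:
    """Draw n women's BA and PD 8-vectors (L quadrants then R quadrants).

    The PD z-score of each (quadrant, side) is ``r * z_BA + sqrt(1-r²) * e``
    with ``r = pd_ba_correlation`` and a residual field ``e`` whose
    correlation is chosen so PD keeps exactly its own intra-breast and
    bilateral correlations. Women with any out-of-range value (BA <= 0 or
    PD outside [0, 100]) are redrawn wholesale, so truncation leaves no
    boundary atoms.
    """
    rho_bil = spec.bilateral_correlation
    root_ba = _kron_root(rho_bil, spec.intra_breast_correlation_BA)
    r = spec.pd_ba_correlation
    r2 = r * r
    if r2 < 1.0:
        rho_resid = (spec.intra_breast_correlation_PD
                     - r2 * spec.intra_breast_correlation_BA) / (1.0 - r2)
        root_e = _kron_root(rho_bil, rho_resid)
    else:
        root_e = np.zeros((8, 8))

    mu_ba = np.tile(np.asarray(spec.quadrant_BA_means, float), 2)
    sd_ba = np.tile(np.asarray(spec.quadrant_BA_sds, float), 2)
    mu_pd = np.tile(np.asarray(spec.quadrant_PD_means, float), 2)
    sd_pd = np.tile(np.asarray(spec.quadrant_PD_sds, float), 2)

    ba = np.empty((n, 8))
    pdv = np.empty((n, 8))
    todo = np.arange(n)
    for _ in range(1000):
        z_ba = rng.standard_normal((todo.size, 8)) @ root_ba.T
        z_e = rng.standard_normal((todo.size, 8)) @ root_e.T
        z_pd = r * z_ba + math.sqrt(max(1.0 - r2, 0.0)) * z_e
        ba[todo] = mu_ba + sd_ba * z_ba
        pdv[todo] = mu_pd + sd_pd * z_pd
        bad = (np.any(ba[todo] <= 0, axis=1)
               | np.any((pdv[todo] < 0) | (pdv[todo] > 100), axis=1))
        todo = todo[bad]
        if todo.size == 0:
            return ba, pdv
    raise ParameterError(
        "could not draw in-range cohort values after 1000 rounds; "
        "means/SDs place too much mass outside the valid range"
    )


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate a cohort of :class:`CohortRecord`, deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_women

    tq_idx = rng.choice(4, size=n, p=np.asarray(spec.tumor_probs, float))
    diseased_side = rng.choice(np.array(["L", "R"]), size=n)

    ba, pdv = _draw_ba_pd(rng, n, spec)

    records = []
    for i in range(n):
        profiles = {}
        for s, side in enumerate(("L", "R")):
            ba_q = {q: ba[i, 4 * s + j] for j, q in enumerate(QUADRANTS)}
            da_q = {q: pdv[i, 4 * s + j] * ba_q[q] / 100.0
                    for j, q in enumerate(QUADRANTS)}
            profiles[side] = QuadrantProfile.from_areas(ba_q, da_q)
        d_side = str(diseased_side[i])
        n_side = "R" if d_side == "L" else "L"
        records.append(CohortRecord(
            woman_id=f"W{i + 1:04d}",
            tumor_quadrant=QUADRANTS[int(tq_idx[i])],
            normal_breast=profiles[n_side],
            diseased_breast=profiles[d_side],
            diseased_side=d_side,
        ))
    return records


def cohort_to_dataframe(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten a cohort to the interchange table: one row per woman with
    ``{L,R}_{UO,UI,LO,LI}_{BA,DA,PD}`` columns."""
    rows = []
    for rec in records:
        row = {"woman_id": rec.woman_id,
               "tumor_quadrant": rec.tumor_quadrant,
               "diseased_side": rec.diseased_side}
        by_side = {rec.diseased_side: rec.diseased_breast}
        by_side["R" if rec.diseased_side == "L" else "L"] = rec.normal_breast
        for side in ("L", "R"):
            prof = by_side[side]
            for q in QUADRANTS:
                if prof is None:
                    row[f"{side}_{q}_BA"] = np.nan
                    row[f"{side}_{q}_DA"] = np.nan
                    row[f"{side}_{q}_PD"] = np.nan
                else:
                    row[f"{side}_{q}_BA"] = prof.ba[q]
                    row[f"{side}_{q}_DA"] = prof.da[q]
                    row[f"{side}_{q}_PD"] = prof.pd[q]
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_dataframe(df: pd.DataFrame) -> list[CohortRecord]:
    """Inverse of :func:`cohort_to_dataframe`."""
    records = []
    for _, row in df.iterrows():
        profiles = {}
        for side in ("L", "R"):
            cols = [f"{side}_{q}_{v}" for q in QUADRANTS for v in ("BA", "DA")]
            if any(c not in row or pd.isna(row[c]) for c in cols):
                profiles[side] = None
                continue
            ba = {q: float(row[f"{side}_{q}_BA"]) for q in QUADRANTS}
            da = {q: float(row[f"{side}_{q}_DA"]) for q in QUADRANTS}
            profiles[side] = QuadrantProfile.from_areas(ba, da)
        d_side = str(row.get("diseased_side", "L"))
        n_side = "R" if d_side == "L" else "L"
        if profiles[n_side] is None:
            raise InputError(
                f"woman {row.get('woman_id')}: normal-breast columns missing"
            )
        records.append(CohortRecord(
            woman_id=str(row["woman_id"]),
            tumor_quadrant=str(row["tumor_quadrant"]),
            normal_breast=profiles[n_side],
            diseased_breast=profiles[d_side],
            diseased_side=d_side,
        ))
    return records


def write_cohort_csv(records: list[CohortRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    return cohort_from_dataframe(pd.read_csv(path))
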