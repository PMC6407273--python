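"""LMS spirometry reference equations, obstruction classification and concordance accounting.

The lower limit of normal (LLN) for a spirometric index such as FEV1/FVC is
the lower fifth percentile of a healthy reference population given sex, age
and height.  Reference distributions are modelled with the LMS method: the
index at standard-normal deviate ``z`` is ``M * (1 + L*S*z)**(1/L)`` (or
``M * exp(S*z)`` when the Box-Cox power ``L`` is zero), where M is the median,
S the coefficient of variation and L the Box-Cox power, all smooth functions
of the covariates.

Airflow obstruction is classified two ways on the same spirometry:

* ``fixed70`` — FEV1/FVC ratio (in percent) strictly below 70.
* ``lln`` — ratio strictly below the subject's LLN.

Smoking strata follow the convention of the analysis: never-smokers have
0 pack-years, ever-smokers more than 5; subjects in between are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DomainError",
    "LmsReference",
    "CrossClassification",
    "ConcordanceStats",
    "default_reference",
    "lms_lln",
    "percent_predicted",
    "classify_obstruction",
    "cross_classification",
    "concordance_stats",
]

SEXES = ("male", "female")
DEFINITIONS = ("fixed70", "lln")
STRATA = ("never", "ever")

#: pack-year bounds delimiting the smoking strata: never = 0, ever > 5.
EVER_SMOKER_MIN_PACK_YEARS = 5.0


class DomainError(ValueError):
    """Raised when (sex, age) falls outside the reference's declared domain."""


@dataclass(frozen=True)
class LmsReference:
    """Per-sex LMS coefficient tables on an age grid, linearly interpolated.

    Parameters
    ----------
    tables
        Mapping sex -> DataFrame with columns ``age``, ``M``, ``S``, ``L``,
        sorted by age.  M carries the units of the index (percent for
        FEV1/FVC), S and L are dimensionless.
    index
        Name of the spirometric index the reference describes.
    height_power
        Optional power on ``height / reference_height`` multiplying M, for
        indices with residual height dependence.  The bundled FEV1/FVC
        reference uses 0 (the ratio is essentially height-free).
    """

    tables: Mapping[str, pd.DataFrame]
    index: str = "FEV1/FVC (%)"
    height_power: float = 0.0
    reference_height: Mapping[str, float] = field(
        default_factory=lambda: {"male": 177.0, "female": 164.0}
    )

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.tables:
                raise ValueError(f"reference is missing a table for sex={sex!r}")
            tab = self.tables[sex]
            missing = {"age", "M", "S", "L"} - set(tab.columns)
            if missing:
                raise ValueError(f"LMS table for {sex!r} lacks columns {sorted(missing)}")
            if not (tab["M"].gt(0).all() and tab["S"].gt(0).all()):
                raise ValueError("M and S must be strictly positive over the grid")
            if not tab["age"].is_monotonic_increasing:
                raise ValueError("age grid must be sorted increasing")

    def age_domain(self, sex: str) -> tuple[float, float]:
        tab = self.tables[sex]
        return float(tab["age"].iloc[0]), float(tab["age"].iloc[-1])

    def coefficients(self, sex, age, height=None):
        """Interpolated (L, M, S) at the given ages; raises outside the grid."""
        sex_arr = np.asarray(sex)
        age_arr = np.asarray(age, dtype=float)
        if sex_arr.ndim == 0 and age_arr.ndim == 0:
            L, M, S = self.coefficients([sex], [age], None if height is None else [height])
            return float(L[0]), float(M[0]), float(S[0])
        sex_arr = np.broadcast_to(sex_arr, age_arr.shape)
        L = np.empty_like(age_arr)
        M = np.empty_like(age_arr)
        S = np.empty_like(age_arr)
        for s in SEXES:
            mask = sex_arr == s
            if not mask.any():
                continue
            lo, hi = self.age_domain(s)
            a = age_arr[mask]
            if np.any((a < lo) | (a > hi)):
                raise DomainError(
                    f"age outside reference domain [{lo}, {hi}] for sex={s!r}"
                )
            tab = self.tables[s]
            grid = tab["age"].to_numpy(dtype=float)
            L[mask] = np.interp(a, grid, tab["L"].to_numpy(dtype=float))
            M[mask] = np.interp(a, grid, tab["M"].to_numpy(dtype=float))
            S[mask] = np.interp(a, grid, tab["S"].to_numpy(dtype=float))
        unknown = ~np.isin(sex_arr, SEXES)
        if unknown.any():
            raise DomainError(f"unknown sex value(s): {set(sex_arr[unknown])}")
        if height is not None and self.height_power != 0.0:
            href = np.where(
                sex_arr == "male",
                self.reference_height["male"],
                self.reference_height["female"],
            )
            M = M * (np.asarray(height, dtype=float) / href) ** self.height_power
        return L, M, S

    def quantile(self, sex, age, height, z):
        """Index value at standard-normal deviate z: M*(1+L*S*z)**(1/L)."""
        L, M, S = self.coefficients(sex, age, height)
        return _lms_quantile(L, M, S, np.asarray(z, dtype=float))


def _lms_quantile(L, M, S, z):
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    near_zero = np.abs(L) < 1e-12
    Lsafe = np.where(near_zero, 1.0, L)
    inner = 1.0 + Lsafe * S * z
    inner = np.maximum(inner, 1e-12)  # Box-Cox support boundary
    boxcox = M * inner ** (1.0 / Lsafe)
    lognormal = M * np.exp(S * z)
    out = np.where(near_zero, lognormal, boxcox)
    if out.ndim == 0:
        return float(out)
    return out


def lms_lln(reference: LmsReference, sex, age, height, percentile: float = 0.05):
    """Lower limit of normal: the LMS quantile at the given lower percentile.

    With the default ``percentile=0.05`` this is the conventional lower fifth
    percentile, z ≈ −1.6449.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    z = stats.norm.ppf(percentile)
    return reference.quantile(sex, age, height, z)


def percent_predicted(reference: LmsReference, sex, age, height, observed):
    """100 × observed / predicted-median for the given covariates."""
    _, M, _ = reference.coefficients(sex, age, height)
    out = 100.0 * np.asarray(observed, dtype=float) / M
    if out.ndim == 0:
        return float(out)
    return out


def default_reference() -> LmsReference:
    """Synthetic-but-plausible FEV1/FVC (%) reference bundled for simulation
    and tests.

    Median ratio declines roughly linearly with age (86→68% male over ages
    18–95, matching the published reference's slope for the ratio), the
    coefficient of variation is ≈ 7.5 %, and the Box-Cox power eases from 1.2
    to 0.8.  The resulting LLN crosses the fixed 70 % cut-off in middle age,
    so fixed-ratio-only cases concentrate in the old and LLN-only cases in
    the young — the qualitative structure that makes the two obstruction
    definitions disagree.  This is *not* the published GLI-2012 spline fit;
    supply a real coefficient table via :func:`spirogwas.io.read_lms_table`
    for production use.
    """
    age = np.arange(18.0, 96.0)
    frac = (age - 18.0) / (95.0 - 18.0)
    L = 1.2 - 0.4 * frac
    S = np.full_like(age, 0.075)
    tables = {}
    for sex, m0 in (("male", 86.0), ("female", 87.0)):
        M = m0 - 0.23 * (age - 18.0)
        tables[sex] = pd.DataFrame({"age": age, "M": M, "S": S, "L": L})
    return LmsReference(tables=tables)


# ---------------------------------------------------------------------------
# classification


def _stratum_from_pack_years(pack_years: np.ndarray) -> np.ndarray:
    stratum = np.full(pack_years.shape, "excluded", dtype=object)
    stratum[pack_years == 0] = "never"
    stratum[pack_years > EVER_SMOKER_MIN_PACK_YEARS] = "ever"
    return stratum


def classify_obstruction(
    cohort, reference: LmsReference, percentile: float = 0.05
) -> pd.DataFrame:
    """Label every subject under both obstruction definitions.

    Returns a DataFrame aligned row-for-row with ``cohort.subjects`` with
    columns ``id, stratum, valid, ratio, lln_value, fixed70, lln``.  Subjects
    with missing or non-positive spirometry get ``valid=False`` and are
    excluded from all downstream counting; comparisons are strict
    (``ratio < 70`` and ``ratio < LLN``), computed at full floating precision.
    """
    subj = cohort.subjects
    fev1 = subj["fev1"].to_numpy(dtype=float)
    fvc = subj["fvc"].to_numpy(dtype=float)
    valid = np.isfinite(fev1) & np.isfinite(fvc) & (fev1 > 0) & (fvc > 0)
    ratio = np.full(len(subj), np.nan)
    ratio[valid] = 100.0 * fev1[valid] / fvc[valid]
    lln_value = np.full(len(subj), np.nan)
    lln_value[valid] = lms_lln(
        reference,
        subj["sex"].to_numpy()[valid],
        subj["age"].to_numpy(dtype=float)[valid],
        subj["height"].to_numpy(dtype=float)[valid],
        percentile=percentile,
    )
    fixed70 = valid & (ratio < 70.0)
    lln = valid & (ratio < lln_value)
    return pd.DataFrame(
        {
            "id": subj["id"].to_numpy(),
            "stratum": _stratum_from_pack_years(subj["pack_years"].to_numpy(dtype=float)),
            "valid": valid,
            "ratio": ratio,
            "lln_value": lln_value,
            "fixed70": fixed70,
            "lln": lln,
        }
    )


# ---------------------------------------------------------------------------
# concordance accounting


@dataclass(frozen=True)
class CrossClassification:
    """2×2 case counts for the two obstruction definitions in one stratum."""

    n: int
    n70: int
    nlln: int
    nboth: int

    def __post_init__(self) -> None:
        if self.nboth > min(self.n70, self.nlln):
            raise ValueError("nboth cannot exceed either marginal case count")
        if self.n_union > self.n:
            raise ValueError("case union cannot exceed the stratum size")

    @property
    def n_union(self) -> int:
        """Subjects obstructed under at least one definition."""
        return self.n70 + self.nlln - self.nboth

    @property
    def n_discordant(self) -> int:
        """Subjects labelled by exactly one definition."""
        return self.n70 + self.nlln - 2 * self.nboth


def cross_classification(labels: pd.DataFrame, stratum: str) -> CrossClassification:
    """Exact case counts for one smoking stratum of a label table."""
    sel = labels[(labels["stratum"] == stratum) & labels["valid"]]
    if sel.empty:
        raise ValueError(f"no labelled subjects in stratum {stratum!r}")
    f70 = sel["fixed70"].to_numpy(dtype=bool)
    lln = sel["lln"].to_numpy(dtype=bool)
    return CrossClassification(
        n=len(sel),
        n70=int(f70.sum()),
        nlln=int(lln.sum()),
        nboth=int((f70 & lln).sum()),
    )


@dataclass(frozen=True)
class ConcordanceStats:
    """Agreement percentages between the two definitions, full precision.

    ``pct_discordant_among_union`` and ``pct_overlap_cases`` are None when no
    subject is a case under either definition (flagged, never silently NaN).
    """

    pct_concordant: float
    pct_discordant: float
    pct_discordant_among_union: float | None
    pct_overlap_cases: float | None

    def rounded(self) -> dict:
        """Display form: nearest-integer percentages, as printed in reports."""
        def r(x):
            return None if x is None else int(round(x))

        return {
            "pct_concordant": r(self.pct_concordant),
            "pct_discordant": r(self.pct_discordant),
            "pct_discordant_among_union": r(self.pct_discordant_among_union),
            "pct_overlap_cases": r(self.pct_overlap_cases),
        }


def concordance_stats(cc: CrossClassification) -> ConcordanceStats:
    """Concordant/discordant percentages of a cross-classification.

    Concordance is over the full stratum; the union-based percentages are
    over subjects obstructed under at least one definition.
    """
    pct_concordant = 100.0 * (cc.n - cc.n_discordant) / cc.n
    pct_discordant = 100.0 * cc.n_discordant / cc.n
    if cc.n_union == 0:
        return ConcordanceStats(pct_concordant, pct_discordant, None, None)
    return ConcordanceStats(
        pct_concordant=pct_concordant,
        pct_discordant=pct_discordant,
        pct_discordant_among_union=100.0 * cc.n_discordant / cc.n_union,
        pct_overlap_cases=100.0 * cc.nboth / cc.n_union,
    )
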