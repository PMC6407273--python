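"""The two resampling simulation studies.

1. *k-fold cohort expansion* — duplicate every subject k times (genotypes,
   covariates and labels verbatim) and re-run the scans.  Point estimates are
   unchanged while standard errors shrink by ≈ 1/√k, so this isolates the
   pure power effect of sample size on hit overlap.

2. *Random case allocation* — a permutation null in which case labels for
   both obstruction definitions are re-dealt uniformly over the subjects of a
   stratum while the three case counts (fixed-ratio cases, LLN cases, and
   their overlap) are preserved exactly.  Re-running both scans on each
   replicate gives the null distribution of hit overlap at any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .gwas import ScanSpec, run_scan
from .overlap import threshold_overlap
from .reference import cross_classification

__all__ = [
    "NullOverlapDistribution",
    "expand_cohort",
    "random_case_allocation",
    "null_overlap_experiment",
]


def expand_cohort(cohort: Cohort, labels: pd.DataFrame, k: int):
    """Duplicate every subject k times (k ≥ 2) with fresh subject ids.

    Rows are tiled block-wise: the full cohort repeated k times, copy r
    getting id suffix ``_d{r}``.
    """
    if k < 2:
        raise ValueError("expansion factor k must be at least 2")
    parts_s, parts_l = [], []
    for r in range(k):
        s = cohort.subjects.copy()
        l = labels.copy()
        s["id"] = s["id"].astype(str) + f"_d{r}"
        l["id"] = l["id"].astype(str) + f"_d{r}"
        parts_s.append(s)
        parts_l.append(l)
    subjects = pd.concat(parts_s, ignore_index=True)
    new_labels = pd.concat(parts_l, ignore_index=True)
    genotypes = np.tile(cohort.genotypes, (k, 1))
    return Cohort(subjects=subjects, genotypes=genotypes,
                  snp_info=cohort.snp_info), new_labels


def random_case_allocation(
    labels: pd.DataFrame, stratum: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Re-deal case labels uniformly within one stratum, preserving margins.

    The observed counts (n70, nlln, nboth) are reproduced exactly: nboth
    subjects receive both labels, n70−nboth the fixed-ratio label only,
    nlln−nboth the LLN label only, everyone else neither.  Genotypes,
    covariates and the other strata are untouched.  The permuted table keeps
    only label columns consistent — ``ratio``/``lln_value`` no longer
    correspond to the flags and are set to NaN.
    """
    cc = cross_classification(labels, stratum)
    out = labels.copy()
    idx = np.flatnonzero(
        (labels["stratum"].to_numpy() == stratum) & labels["valid"].to_numpy()
    )
    if cc.n_union > idx.size:
        raise ValueError("case counts infeasible for stratum size")
    chosen = rng.choice(idx, size=cc.n_union, replace=False)
    both = chosen[: cc.nboth]
    only70 = chosen[cc.nboth: cc.n70]
    onlylln = chosen[cc.n70: cc.n_union]
    f70 = np.zeros(len(labels), dtype=bool)
    lln = np.zeros(len(labels), dtype=bool)
    f70[both] = f70[only70] = True
    lln[both] = lln[onlylln] = True
    out.loc[out.index[idx], "fixed70"] = f70[idx]
    out.loc[out.index[idx], "lln"] = lln[idx]
    out.loc[out.index[idx], ["ratio", "lln_value"]] = np.nan
    new_cc = cross_classification(out, stratum)
    assert (new_cc.n70, new_cc.nlln, new_cc.nboth) == (cc.n70, cc.nlln, cc.nboth)
    return out


@dataclass(frozen=True)
class NullOverlapDistribution:
    """Replicate-wise overlap percentages under random case allocation.

    A replicate whose hit union is empty contributes 0 % overlap (there is no
    agreement to credit).
    """

    threshold: float
    replicates: int
    overlap_pcts: tuple[float, ...]
    seed: int

    def __post_init__(self):
        if len(self.overlap_pcts) != self.replicates:
            raise ValueError("one overlap percentage per replicate required")

    @property
    def min(self) -> float:
        return min(self.overlap_pcts)

    @property
    def max(self) -> float:
        return max(self.overlap_pcts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.overlap_pcts))


def null_overlap_experiment(
    cohort: Cohort,
    labels: pd.DataFrame,
    stratum: str = "never",
    replicates: int = 10,
    thresholds=(1e-4,),
    seed: int = 0,
) -> dict[float, NullOverlapDistribution]:
    """Random-case-allocation null for the between-definition hit overlap.

    Each replicate permutes the labels (margins preserved), re-runs both
    definition scans with their covariate conventions on ``stratum``, and
    records the union-fraction overlap at every threshold.
    """
    rng = np.random.default_rng([seed, 5])
    pcts: dict[float, list[float]] = {t: [] for t in thresholds}
    for _ in range(replicates):
        perm = random_case_allocation(labels, stratum, rng)
        scan70 = run_scan(cohort, perm, ScanSpec("fixed70", stratum))
        scanlln = run_scan(cohort, perm, ScanSpec("lln", stratum))
        for rep in threshold_overlap(scan70, scanlln, thresholds):
            pct = rep.pct_overlap_of_union if rep.pct_overlap_of_union is not None else 0.0
            pcts[rep.threshold].append(pct)
    return {
        t: NullOverlapDistribution(
            threshold=t, replicates=replicates, overlap_pcts=tuple(v), seed=seed
        )
        for t, v in pcts.items()
    }
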