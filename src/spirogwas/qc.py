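"""SNP-level quality control: call rate, minor allele frequency, exact
Hardy-Weinberg test, and the combined filter.

Defaults match standard genotyped-array practice: call rate ≥ 95 %, MAF ≥ 1 %,
HWE p ≥ 1e−4.  QC is computed once on the whole genotyped sample (not per
smoking stratum); stratification happens downstream in the scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, Cohort

__all__ = [
    "QcThresholds",
    "snp_call_rate",
    "minor_allele_frequency",
    "hwe_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-4

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def snp_call_rate(genotypes: np.ndarray) -> float:
    """Fraction of non-missing calls in one genotype column."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype column")
    return float(np.count_nonzero(g != MISSING) / g.size)


def minor_allele_frequency(genotypes: np.ndarray) -> float:
    """Allele frequency of the rarer allele among non-missing genotypes."""
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("no non-missing genotypes")
    f = float(g.mean() / 2.0)
    return min(f, 1.0 - f)


def _hwe_exact(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional HWE test (two-sided, by probability ordering).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration.  Probabilities follow the standard recurrence in the
    heterozygote count, which is numerically stable for array-scale samples.
    """
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # feasible het counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != het_min:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 * hom_rare+1 * hom_common+1)
    h = mid
    val = 1.0
    while h - 2 >= het_min:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        val *= h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        probs[h] = val
    h = mid
    val = 1.0
    while h + 2 <= het_max:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        val *= 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
        probs[h] = val
    total = sum(probs.values())
    obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _hwe_chisq(n_het: int, n_hom1: int, n_hom2: int) -> float:
    n = n_het + n_hom1 + n_hom2
    p = (2 * n_hom1 + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    x2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x2, 1))


def hwe_test(genotypes: np.ndarray, exact_max_n: int = 100_000) -> float:
    """Hardy-Weinberg p-value for one genotype column.

    Uses the exact conditional test by default, falling back to the 1-df
    chi-square only when the non-missing sample exceeds ``exact_max_n``.
    Monomorphic columns return 1.0 by convention.
    """
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("no non-missing genotypes")
    n_hom1 = int(np.count_nonzero(g == 2))
    n_het = int(np.count_nonzero(g == 1))
    n_hom2 = int(np.count_nonzero(g == 0))
    if n_het + min(n_hom1, n_hom2) == 0:
        return 1.0
    if g.size > exact_max_n:
        return _hwe_chisq(n_het, n_hom1, n_hom2)
    return _hwe_exact(n_het, n_hom1, n_hom2)


def apply_qc(
    cohort: Cohort, thresholds: QcThresholds = QcThresholds()
) -> tuple[Cohort, pd.DataFrame]:
    """Remove SNPs failing any filter; subjects are untouched.

    Returns the filtered cohort and a per-SNP report with columns
    ``snp_id, call_rate, maf, hwe_p, pass_call_rate, pass_maf, pass_hwe,
    pass``.  Idempotent: re-running on the output removes nothing further.
    """
    m = cohort.n_snps
    call_rate = np.empty(m)
    maf = np.empty(m)
    hwe_p = np.empty(m)
    for j in range(m):
        col = cohort.genotypes[:, j]
        call_rate[j] = snp_call_rate(col)
        if call_rate[j] == 0.0:
            maf[j] = 0.0
            hwe_p[j] = 1.0
            continue
        maf[j] = minor_allele_frequency(col)
        hwe_p[j] = hwe_test(col)
    pass_cr = call_rate >= thresholds.min_call_rate
    pass_maf = maf >= thresholds.min_maf
    pass_hwe = hwe_p >= thresholds.min_hwe_p
    ok = pass_cr & pass_maf & pass_hwe
    report = pd.DataFrame(
        {
            "snp_id": cohort.snp_info["snp_id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_cr,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "pass": ok,
        }
    )
    if not ok.any():
        import warnings

        warnings.warn("all SNPs removed by QC; downstream scans will be empty")
    return cohort.subset_snps(ok), report
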