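"""Agreement between two GWAS scans: thresholded hit-set overlap expressed as
a fraction of the union (Jaccard, in percent), Bonferroni thresholds, and
Pearson correlation of per-SNP p-values and odds ratios.

Hits are strict: a SNP with p exactly equal to the threshold is not a hit.
Correlations are computed on raw p-values and raw ORs by default — the raw-OR
correlation is dominated by extreme odds ratios, so log/−log10 variants are
exposed via ``scale`` — and the scale used is recorded in the report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapReport",
    "AgreementReport",
    "threshold_overlap",
    "bonferroni_threshold",
    "format_threshold",
    "agreement",
    "cross_stratum_overlap",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass(frozen=True)
class OverlapReport:
    """Hit sets of two scans below one p-value threshold and their overlap.

    ``pct_overlap_of_union`` is 100·|A∩B| / |A∪B|, None when the union is
    empty.
    """

    threshold: float
    n_hits_a: int
    n_hits_b: int
    n_overlap: int
    pct_overlap_of_union: float | None
    hits_a: tuple
    hits_b: tuple

    @property
    def n_union(self) -> int:
        return self.n_hits_a + self.n_hits_b - self.n_overlap

    @staticmethod
    def from_counts(threshold, n_hits_a, n_hits_b, n_overlap,
                    hits_a=(), hits_b=()) -> "OverlapReport":
        if n_overlap > min(n_hits_a, n_hits_b):
            raise ValueError("overlap cannot exceed either hit count")
        union = n_hits_a + n_hits_b - n_overlap
        pct = 100.0 * n_overlap / union if union > 0 else None
        return OverlapReport(threshold, n_hits_a, n_hits_b, n_overlap, pct,
                             tuple(hits_a), tuple(hits_b))


@dataclass(frozen=True)
class AgreementReport:
    r_pvalue: float
    r_or: float
    n_snps: int
    scale: str = "raw"


def _result_frame(scan) -> pd.DataFrame:
    return scan.results if hasattr(scan, "results") else scan


def threshold_overlap(scan_a, scan_b, thresholds=DEFAULT_THRESHOLDS) -> list[OverlapReport]:
    """Per threshold: hit sets {p < t} of each scan on their common SNP
    universe, the intersection, and the union-fraction percentage."""
    a = _result_frame(scan_a)
    b = _result_frame(scan_b)
    common = pd.Index(a["snp_id"]).intersection(pd.Index(b["snp_id"]))
    if len(common) == 0:
        raise ValueError("the two scans share no SNPs")
    pa = a.set_index("snp_id").loc[common, "p"]
    pb = b.set_index("snp_id").loc[common, "p"]
    reports = []
    for t in thresholds:
        hits_a = set(pa.index[pa < t])
        hits_b = set(pb.index[pb < t])
        inter = hits_a & hits_b
        reports.append(
            OverlapReport.from_counts(
                t, len(hits_a), len(hits_b), len(inter),
                hits_a=sorted(hits_a), hits_b=sorted(hits_b),
            )
        )
    return reports


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests (e.g. 0.05 / 227,981 ≈ 2.19e−7)."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def format_threshold(t: float, sig: int = 3) -> str:
    """Display form of a p-value threshold, e.g. 2.193e-07 → '2.19 × 10⁻⁷'."""
    if t >= 0.001:
        return f"{t:g}"
    mant, exp = f"{t:.{sig - 1}e}".split("e")
    exp_i = int(exp)
    sup = str(exp_i).translate(str.maketrans("-0123456789", "⁻⁰¹²³⁴⁵⁶⁷⁸⁹"))
    return f"{mant} × 10{sup}"


def agreement(scan_a, scan_b, scale: str = "raw") -> AgreementReport:
    """Pearson correlation of per-SNP p-values and ORs between two scans.

    ``scale`` is ``"raw"`` (as conventionally reported) or ``"log"``
    (−log10 p and log OR).  SNPs lacking a converged estimate in either scan
    are dropped pairwise.
    """
    a = _result_frame(scan_a).set_index("snp_id")
    b = _result_frame(scan_b).set_index("snp_id")
    common = a.index.intersection(b.index)
    pa, pb = a.loc[common, "p"].to_numpy(), b.loc[common, "p"].to_numpy()
    oa, ob = a.loc[common, "or_"].to_numpy(), b.loc[common, "or_"].to_numpy()
    ok = np.isfinite(pa) & np.isfinite(pb) & np.isfinite(oa) & np.isfinite(ob)
    pa, pb, oa, ob = pa[ok], pb[ok], oa[ok], ob[ok]
    if pa.size < 3:
        raise ValueError("need at least 3 jointly estimated SNPs")
    if scale == "log":
        pa, pb = -np.log10(pa), -np.log10(pb)
        oa, ob = np.log(oa), np.log(ob)
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log'")
    for v in (pa, pb, oa, ob):
        if np.ptp(v) == 0.0:
            raise ValueError("zero variance in one of the correlated vectors")
    r_p = float(stats.pearsonr(pa, pb).statistic)
    r_or = float(stats.pearsonr(oa, ob).statistic)
    return AgreementReport(r_pvalue=r_p, r_or=r_or, n_snps=int(pa.size), scale=scale)


def cross_stratum_overlap(scans: dict, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """All pairwise overlap + agreement reports across the four scans.

    ``scans`` maps (definition, stratum) → ScanSummary; the 6 unordered pairs
    are emitted, keyed by the sorted key pair.
    """
    if len(scans) != 4:
        raise ValueError("expected the four definition × stratum scans")
    out = {}
    for (ka, sa), (kb, sb) in itertools.combinations(sorted(scans.items()), 2):
        out[(ka, kb)] = {
            "overlap": threshold_overlap(sa, sb, thresholds),
            "agreement": agreement(sa, sb),
        }
    return out
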