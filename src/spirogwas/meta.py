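"""Fixed-effects inverse-variance meta-analysis, direction-of-effect
encoding, the replication criterion, and cis-eQTL linear scanning.

Meta-analysis pools per-cohort log-odds estimates with weights 1/SE²; the
pooled p-value is the Wald test of beta/SE (the METAL convention; a
sample-size/z-score weighted variant is available behind ``scheme``).
Heterogeneity is Cochran's Q with I² = max(0, 100·(Q − df)/Q).

Direction strings encode each cohort's odds ratio as '+' (> 1.05),
'−' (< 0.95) or '0' (inside the closed band [0.95, 1.05], "no effect"); a
'0' is direction-compatible with either sign for replication calling.

cis-eQTL scanning regresses probe expression on allele count plus covariates
(OLS) for every probe annotated within 2 Mb of the SNP (a 4 Mb window), with
a Bonferroni threshold of 0.05 / number of probes tested in the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import wald_test

__all__ = [
    "CohortEstimate",
    "MetaResult",
    "fixed_effects_meta",
    "direction_string",
    "replication_call",
    "cis_eqtl_scan",
    "CIS_WINDOW_BP",
]

CIS_WINDOW_BP = 2_000_000  # each side of the SNP
ZERO_BAND = (0.95, 1.05)


@dataclass(frozen=True)
class CohortEstimate:
    cohort_id: str
    snp_id: str
    beta: float
    se: float
    n: int = 0

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    snp_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    q_stat: float
    i2: float
    direction: str
    cohorts: tuple[str, ...]


def fixed_effects_meta(estimates: Sequence[CohortEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pool of one SNP's cohort estimates.

    Estimates must already share effect-allele orientation.  With weights
    w_i = 1/se_i²: beta = Σwβ/Σw, se = (Σw)^(−1/2), Q = Σw(β_i − beta)²,
    I² = max(0, 100·(Q − (k−1))/Q).
    """
    if len(estimates) == 0:
        raise ValueError("at least one cohort estimate required")
    snp_ids = {e.snp_id for e in estimates}
    if len(snp_ids) != 1:
        raise ValueError(f"estimates mix SNPs: {sorted(snp_ids)}")
    beta = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    w = 1.0 / se**2
    beta_meta = float((w * beta).sum() / w.sum())
    se_meta = float(w.sum() ** -0.5)
    q = float((w * (beta - beta_meta) ** 2).sum())
    df = len(estimates) - 1
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        snp_id=estimates[0].snp_id,
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_meta=wald_test(beta_meta, se_meta),
        q_stat=q,
        i2=i2,
        direction=direction_string([float(np.exp(b)) for b in beta]),
        cohorts=tuple(e.cohort_id for e in estimates),
    )


def direction_string(odds_ratios: Sequence[float], zero_band=ZERO_BAND) -> str:
    """One character per cohort, in the given order: '+', '−' (U+2212) or '0'.

    The no-effect band is closed: OR exactly 0.95 or 1.05 encodes as '0'.
    """
    lo, hi = zero_band
    chars = []
    for o in odds_ratios:
        if not o > 0:
            raise ValueError("odds ratios must be positive")
        if lo <= o <= hi:
            chars.append("0")
        elif o > hi:
            chars.append("+")
        else:
            chars.append("−")
    return "".join(chars)


def _directions_consistent(direction: str) -> bool:
    signs = {c for c in direction if c in "+−-"}
    return len(signs - {"0"}) <= 1


def replication_call(
    meta: MetaResult, n_candidates: int, alpha: float = 0.05, directions: str | None = None
) -> dict:
    """Bonferroni + direction replication rule.

    Replicated iff p_meta < alpha/n_candidates and no two cohorts have
    opposing signs ('0' entries are compatible with either sign).
    ``directions`` defaults to the meta result's own string — pass the
    all-cohorts string (e.g. discovery + validation) to apply the rule across
    every cohort considered.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be at least 1")
    threshold = alpha / n_candidates
    direction = directions if directions is not None else meta.direction
    return {
        "replicated": bool(meta.p_meta < threshold and _directions_consistent(direction)),
        "threshold": threshold,
        "direction_consistent": _directions_consistent(direction),
    }


def _ols(X: np.ndarray, y: np.ndarray):
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k or n <= k:
        return None
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), n - k


def cis_eqtl_scan(
    snp_id: str,
    snp_chromosome: int,
    snp_position: int,
    genotype: np.ndarray,
    expression: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    window: int = CIS_WINDOW_BP,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS eQTL scan of one SNP against every probe within ±``window`` bp.

    ``expression`` is probes × subjects; ``genotype`` is the allele-count
    vector aligned with the expression columns (missing < 0, dropped
    listwise); ``covariates`` (subjects × variables, numeric or 'sex'
    strings) are adjusted for.  Returns one row per cis probe with slope, SE,
    t-test p, distance, and a ``significant`` flag at 0.05 / n_probes_tested.
    An empty frame (no probes in the window) is not an error.
    """
    ann = probe_annotation
    cis = ann[
        (ann["chromosome"].to_numpy() == snp_chromosome)
        & (np.abs(ann["position"].to_numpy() - snp_position) <= window)
    ]
    columns = ["snp_id", "probe_id", "distance", "slope", "se", "p", "n",
               "bonferroni_threshold", "significant"]
    if cis.empty:
        return pd.DataFrame(columns=columns)
    g = np.asarray(genotype, dtype=float)
    obs = g >= 0
    covs = np.empty((len(g), 0))
    if covariates is not None:
        cols = []
        for c in covariates.columns:
            v = covariates[c].to_numpy()
            if v.dtype == object:
                v = (v == "male").astype(float)
            cols.append(np.asarray(v, dtype=float))
        covs = np.column_stack(cols)
    bonf = alpha / len(cis)
    rows = []
    for _, probe in cis.iterrows():
        y = expression.loc[probe["probe_id"]].to_numpy(dtype=float)
        ok = obs & np.isfinite(y)
        X = np.column_stack([np.ones(ok.sum()), g[ok], covs[ok]])
        fit = _ols(X, y[ok])
        if fit is None:
            rows.append((snp_id, probe["probe_id"],
                         int(probe["position"] - snp_position),
                         np.nan, np.nan, np.nan, int(ok.sum()), bonf, False))
            continue
        beta, se, dof = fit
        p = 2.0 * float(stats.t.sf(abs(beta[1] / se[1]), dof))
        rows.append((snp_id, probe["probe_id"],
                     int(probe["position"] - snp_position),
                     float(beta[1]), float(se[1]), p, int(ok.sum()), bonf, p < bonf))
    return pd.DataFrame(rows, columns=columns)
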