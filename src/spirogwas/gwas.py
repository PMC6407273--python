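"""Per-SNP additive-model logistic GWAS, from first principles.

Each SNP is tested with a logistic regression of case status on the allele
count (0/1/2) plus a stratum-specific covariate set, fitted by iteratively
reweighted least squares (Newton scoring with step-halving).  Inference is
the Wald test — the squared coefficient-to-SE ratio against chi-square(1) —
matching the convention of the standard GWAS tooling this engine emulates;
a likelihood-ratio test is available behind a flag.

Covariate conventions for the two obstruction definitions:

* fixed-ratio (< 70 %) models adjust for sex, age and height;
* LLN models carry no such covariates (sex, age and height already enter the
  LLN calculation);
* ever-smoker models additionally adjust for pack-years and current smoking.

The effect allele is the minor allele within the analysed stratum; when the
counted allele is the major one, the coefficient sign is flipped.  Missing
genotypes are dropped listwise per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import MISSING, Cohort
from .reference import DEFINITIONS, STRATA

__all__ = [
    "LogisticFit",
    "ScanSpec",
    "ScanSummary",
    "SeparationError",
    "SingularDesignError",
    "fit_logistic",
    "wald_test",
    "run_scan",
    "interaction_scan",
    "genomic_lambda",
    "default_covariates",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ≈ 0.454936


class SingularDesignError(np.linalg.LinAlgError):
    pass


class SeparationError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    loglik: float
    n_iter: int
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _check_design(X: np.ndarray, names):
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} observations cannot identify {k} parameters")
    const = [
        names[j]
        for j in range(1, k)
        if np.ptp(X[:, j]) == 0.0
    ]
    if const:
        raise SingularDesignError(f"constant non-intercept column(s): {const}")
    # rank check via QR; name the dependent columns
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in range(k) if diag[j] <= tol]
    if bad:
        raise SingularDesignError(f"collinear design column(s): {bad}")


def _loglik(y, eta):
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
    column_names=None,
    check: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS.

    ``X`` must include the intercept as its first column.  Convergence is a
    relative log-likelihood change below ``tol`` (default 1e−10) within
    ``max_iter`` (default 50) Newton iterations; the covariance is the inverse
    observed Fisher information at the optimum.  Perfect separation yields
    ``converged=False`` with a diagnostic message; a singular design raises
    :class:`SingularDesignError` naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(k)]
    if check:
        _check_design(X, names)

    beta = np.zeros(k)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        beta[0] = np.log(ybar / (1.0 - ybar))
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    message = ""
    H = None
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (X.T * w) @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            message = "information matrix singular (likely separation)"
            break
        # step-halving to guarantee likelihood ascent
        new_ll = -np.inf
        for half in range(16):
            cand = beta + step
            eta_c = X @ cand
            new_ll = _loglik(y, eta_c)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = cand, eta_c
        if abs(new_ll - ll) < tol * (abs(new_ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged and not message:
        if np.max(np.abs(beta)) > 15.0:
            message = "no convergence; coefficients diverging (possible perfect separation)"
        else:
            message = f"no convergence in {max_iter} iterations"
    mu = expit(X @ beta)
    if converged:
        # complete separation: likelihood plateaus at 0 with all fitted
        # probabilities at their bounds — not a usable optimum
        ones, zeros = mu[y == 1.0], mu[y == 0.0]
        if ((ones.size == 0 or ones.min() > 1 - 1e-6)
                and (zeros.size == 0 or zeros.max() < 1e-6)):
            converged = False
            message = "perfect separation: fitted probabilities at 0/1"
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
        message = message or "information matrix singular at optimum"
    return LogisticFit(beta=beta, cov=cov, converged=converged,
                       loglik=_loglik(y, X @ beta), n_iter=it, message=message)


def wald_test(beta: float, se: float):
    """Two-sided p-value of (beta/se)² against chi-square with 1 df."""
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise ValueError("standard error must be positive")
    out = stats.chi2.sf((np.asarray(beta, dtype=float) / se_arr) ** 2, 1)
    return float(out) if out.ndim == 0 else out


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi-square(1) statistic of
    the p-values divided by the null median (≈ 0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)


def default_covariates(definition: str, stratum: str) -> tuple[str, ...]:
    """Stratum/definition covariate conventions (see module docstring)."""
    base: tuple[str, ...] = ("sex", "age", "height") if definition == "fixed70" else ()
    if stratum == "ever":
        base = base + ("pack_years", "current_smoker")
    return base


@dataclass(frozen=True)
class ScanSpec:
    """One GWAS: obstruction definition, smoking stratum, covariate set."""

    definition: str
    stratum: str
    covariates: tuple[str, ...] | None = None  # None → conventions above

    def __post_init__(self):
        if self.definition not in DEFINITIONS:
            raise ValueError(f"definition must be one of {DEFINITIONS}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")

    def resolved_covariates(self) -> tuple[str, ...]:
        if self.covariates is None:
            return default_covariates(self.definition, self.stratum)
        return tuple(self.covariates)


@dataclass
class ScanSummary:
    spec: ScanSpec
    results: pd.DataFrame
    lambda_gc: float
    n_cases: int
    n_controls: int


_RESULT_COLUMNS = [
    "snp_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "n_used", "beta", "se", "or_", "p", "converged",
]


def _covariate_matrix(subjects: pd.DataFrame, covariates, idx) -> np.ndarray:
    cols = []
    for c in covariates:
        v = subjects[c].to_numpy()
        if v.dtype == object:  # sex
            v = (v == "male").astype(float)
        cols.append(np.asarray(v, dtype=float)[idx])
    if not cols:
        return np.empty((len(idx), 0))
    return np.column_stack(cols)


def _fit_snp(y, g, C, names):
    """Fit one SNP; returns (beta_g, se_g, p, converged) on the allele-count
    coding passed in.  Degenerate genotype columns return NaNs."""
    if np.ptp(g) == 0.0:
        return np.nan, np.nan, np.nan, False
    X = np.column_stack([np.ones_like(y), g, C])
    try:
        fit = fit_logistic(X, y, column_names=names, check=False)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, False
    se = float(np.sqrt(fit.cov[1, 1])) if np.isfinite(fit.cov[1, 1]) else np.nan
    if not fit.converged or not np.isfinite(se) or se <= 0:
        return float(fit.beta[1]), se, np.nan, False
    beta = float(fit.beta[1])
    return beta, se, wald_test(beta, se), True


def run_scan(cohort: Cohort, labels: pd.DataFrame, spec: ScanSpec) -> ScanSummary:
    """One full GWAS over all SNPs of a (QC'd) cohort.

    Restricted to valid subjects of ``spec.stratum``; case status is the
    ``spec.definition`` flag.  Per SNP: listwise deletion of missing
    genotypes, orientation to the in-sample minor allele, logistic fit, Wald
    p.  ``lambda_gc`` is computed over converged SNPs only.
    """
    sel = (labels["stratum"].to_numpy() == spec.stratum) & labels["valid"].to_numpy()
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"stratum {spec.stratum!r} is empty")
    y_all = labels[spec.definition].to_numpy(dtype=bool)[idx].astype(float)
    n_cases = int(y_all.sum())
    n_controls = int(idx.size - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"stratum {spec.stratum!r} needs at least one case and one control "
            f"(cases={n_cases}, controls={n_controls})"
        )
    covariates = spec.resolved_covariates()
    C_all = _covariate_matrix(cohort.subjects, covariates, idx)
    names = ["intercept", "genotype", *covariates]

    info = cohort.snp_info
    a1 = info["allele1"].to_numpy()
    a2 = info["allele2"].to_numpy()
    G = cohort.genotypes[idx, :]

    rows = []
    for j in range(cohort.n_snps):
        g = G[:, j]
        obs = g != MISSING
        gg = g[obs].astype(float)
        if gg.size == 0:
            rows.append((info["snp_id"].iloc[j], np.nan, np.nan, np.nan, 0,
                         np.nan, np.nan, False, a1[j], a2[j]))
            continue
        y = y_all[obs]
        C = C_all[obs]
        freq1 = gg.mean() / 2.0
        if freq1 <= 0.5:
            eff, other, eaf = a1[j], a2[j], freq1
            flip = False
        else:
            eff, other, eaf = a2[j], a1[j], 1.0 - freq1
            flip = True
        if np.ptp(y) == 0.0:
            beta, se, p, conv = np.nan, np.nan, np.nan, False
        else:
            beta, se, p, conv = _fit_snp(y, gg, C, names)
        if flip and np.isfinite(beta):
            beta = -beta
        rows.append((info["snp_id"].iloc[j], eaf, beta, se, int(gg.size), p,
                     np.exp(beta) if np.isfinite(beta) else np.nan, conv, eff, other))

    results = pd.DataFrame(
        rows,
        columns=["snp_id", "eaf", "beta", "se", "n_used", "p", "or_",
                 "converged", "effect_allele", "other_allele"],
    )
    results.insert(1, "chromosome", info["chromosome"].to_numpy())
    results.insert(2, "position", info["position"].to_numpy())
    results = results[_RESULT_COLUMNS]

    p_conv = results.loc[results["converged"], "p"].to_numpy(dtype=float)
    lam = genomic_lambda(p_conv) if p_conv.size else np.nan
    return ScanSummary(spec=spec, results=results, lambda_gc=lam,
                       n_cases=n_cases, n_controls=n_controls)


INTERACTION_COVARIATES = ("sex", "age", "height", "pack_years", "current_smoker")


def interaction_scan(
    cohort: Cohort,
    labels: pd.DataFrame,
    definition: str,
    snp_indices,
    covariates: tuple[str, ...] = INTERACTION_COVARIATES,
) -> pd.DataFrame:
    """SNP × ever-smoking interaction tests on the pooled never+ever sample.

    Model: case ~ genotype + ever + genotype·ever + covariates (the union
    covariate set by default).  Returns one row per SNP with the interaction
    coefficient, its SE and Wald p.
    """
    sel = np.isin(labels["stratum"].to_numpy(), STRATA) & labels["valid"].to_numpy()
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("no subjects in the never/ever strata")
    ever = (labels["stratum"].to_numpy()[idx] == "ever").astype(float)
    y_all = labels[definition].to_numpy(dtype=bool)[idx].astype(float)
    C_all = _covariate_matrix(cohort.subjects, covariates, idx)
    names = ["intercept", "genotype", "ever", "genotype_x_ever", *covariates]

    rows = []
    for j in np.atleast_1d(np.asarray(snp_indices, dtype=int)):
        g = cohort.genotypes[idx, j]
        obs = g != MISSING
        gg = g[obs].astype(float)
        X = np.column_stack([
            np.ones(obs.sum()), gg, ever[obs], gg * ever[obs], C_all[obs],
        ])
        fit = fit_logistic(X, y_all[obs], column_names=names)
        se = float(np.sqrt(fit.cov[3, 3]))
        beta = float(fit.beta[3])
        p = wald_test(beta, se) if fit.converged and se > 0 else np.nan
        rows.append((cohort.snp_info["snp_id"].iloc[j], beta, se, p, fit.converged))
    return pd.DataFrame(
        rows, columns=["snp_id", "beta_interaction", "se_interaction",
                       "p_interaction", "converged"]
    )
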