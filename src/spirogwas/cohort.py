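"""Synthetic cohort generator.

Emulates the structure of a population-based spirometry GWAS sample: two
smoking strata (never-smokers with 0 pack-years, ever-smokers with more than
5), independent biallelic SNPs in Hardy-Weinberg proportions, covariates in
realistic ranges, and an FEV1/FVC ratio generated through the *same* LMS
reference later used for classification, so that the concordance of the two
obstruction definitions is controlled by the age/height dispersion of the
sample rather than assumed.

Genetic effects on obstruction are planted on a latent liability: each
subject's ratio z-score is Normal(0, spirometry_noise²) minus the summed
allele-count × scaled-log-odds shifts of the causal SNPs.  Planted log-odds
are divided by 1.702 (the classical probit↔logit scale factor) so that a
downstream logistic regression on case status recovers approximately the
planted per-allele log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import DEFINITIONS, LmsReference, DomainError

__all__ = [
    "CausalSnp",
    "SimConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_expression",
    "plant_label_effects",
]

MISSING = -1  # genotype sentinel, distinct from homozygous reference
LIABILITY_LOGIT_SCALE = 1.702

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CausalSnp:
    """A SNP with a planted per-allele effect on airflow obstruction.

    ``affected_definitions`` — subset of {"fixed70", "lln"}.  SNPs affecting
    both act through the shared latent ratio; definition-specific SNPs act
    through a post-classification label channel (see `plant_label_effects`).
    """

    snp_index: int
    log_odds_per_allele: float
    affected_definitions: frozenset = frozenset(DEFINITIONS)

    def __post_init__(self):
        bad = set(self.affected_definitions) - set(DEFINITIONS)
        if bad:
            raise ValueError(f"unknown definitions: {sorted(bad)}")
        if not self.affected_definitions:
            raise ValueError("affected_definitions must be non-empty")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-cohort generator; the seed fully determines
    the output (sub-streams are derived deterministically per stage)."""

    n_subjects: int = 9925
    n_snps: int = 10_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal_snps: tuple[CausalSnp, ...] = ()
    stratum_mix: float = 0.511          # fraction of never-smokers
    pack_years_shape: float = 1.3       # ever-smokers: offset + Gamma(shape, scale)
    pack_years_scale: float = 9.2
    pack_years_offset: float = 5.0
    pack_years_log_odds: float = 0.02   # latent obstruction effect per pack-year
    age_range: tuple[float, float] = (18.0, 89.0)
    age_mean: float | None = 46.0       # None → uniform over age_range
    age_sd: float = 14.0
    height_mean: dict = field(default_factory=lambda: {"male": 181.0, "female": 168.0})
    height_sd: float = 7.0
    height_range: tuple[float, float] = (140.0, 210.0)
    male_fraction: float = 0.40
    current_smoker_fraction: float = 0.45
    asthma_fraction: float = 0.08
    spirometry_noise: float = 1.15      # SD of the latent ratio z-score
    missing_genotype_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        if not 0.0 <= self.stratum_mix <= 1.0:
            raise ValueError("stratum_mix must be in [0, 1]")
        for c in self.causal_snps:
            if not 0 <= c.snp_index < self.n_snps:
                raise ValueError(f"causal snp_index {c.snp_index} out of range")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class Cohort:
    """Subjects, genotypes and SNP annotation — the unit every stage consumes.

    ``genotypes`` holds additive allele-1 counts (int8, shape subjects × SNPs)
    with ``MISSING`` (−1) for no-calls; rows correspond one-to-one, in order,
    with ``subjects``.
    """

    subjects: pd.DataFrame
    genotypes: np.ndarray
    snp_info: pd.DataFrame

    def __post_init__(self):
        if self.genotypes.shape != (len(self.subjects), len(self.snp_info)):
            raise ValueError(
                "genotype matrix shape does not match subjects × snp_info"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snp_info)

    def subset_snps(self, keep: np.ndarray) -> "Cohort":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return Cohort(
            subjects=self.subjects,
            genotypes=self.genotypes[:, idx],
            snp_info=self.snp_info.iloc[idx].reset_index(drop=True),
        )


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stage])


def simulate_genotypes(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Independent biallelic SNPs in Hardy-Weinberg proportions.

    Each SNP's allele-1 frequency is drawn uniformly from ``maf_range``;
    genotypes are Binomial(2, maf) counts of allele 1; no-calls are applied
    independently at ``missing_genotype_rate``.
    """
    rng = _rng(config.seed, 1)
    n, m = config.n_subjects, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    geno = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    if config.missing_genotype_rate > 0:
        miss = rng.random(size=(n, m)) < config.missing_genotype_rate
        geno[miss] = MISSING
    chrom = (np.arange(m) % 22) + 1
    pos = 1_000_000 + (np.arange(m) // 22) * 10_000
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    snp_info = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(m)],
            "chromosome": chrom,
            "position": pos,
            "allele1": _BASES[a_idx],
            "allele2": _BASES[b_idx],
            "maf_true": maf,
        }
    )
    return geno, snp_info


def _simulate_fvc(rng, sex, age, height):
    """Plausible FVC (L) from classical linear reference equations + noise."""
    male = sex == "male"
    h_m = height / 100.0
    pred = np.where(
        male,
        5.76 * h_m - 0.026 * age - 4.34,
        4.43 * h_m - 0.026 * age - 2.89,
    )
    fvc = pred + rng.normal(0.0, 0.4, size=len(age))
    return np.maximum(fvc, 1.0)


def simulate_cohort(config: SimConfig, reference: LmsReference) -> Cohort:
    """Draw a full cohort: covariates, smoking strata, genotypes and
    spirometry consistent with the supplied LMS reference.

    The latent ratio z-score of subject *i* is
    ``Normal(0, spirometry_noise²) − Σ_j g_ij · β_j / 1.702`` over causal SNPs
    *j* that affect both definitions; the FEV1/FVC value is the reference's
    LMS quantile at that z, and FEV1 is derived from a separately simulated
    FVC so that ``fev1 ≤ fvc`` always holds.
    """
    lo_m, hi_m = reference.age_domain("male")
    lo_f, hi_f = reference.age_domain("female")
    if config.age_range[0] < max(lo_m, lo_f) or config.age_range[1] > min(hi_m, hi_f):
        raise DomainError(
            f"configured age range {config.age_range} exceeds the reference domain"
        )

    n = config.n_subjects
    rng = _rng(config.seed, 2)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female").astype(object)
    if config.age_mean is None:
        age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    else:
        age = np.clip(
            rng.normal(config.age_mean, config.age_sd, size=n),
            config.age_range[0], config.age_range[1],
        )
    mu_h = np.where(sex == "male", config.height_mean["male"], config.height_mean["female"])
    height = np.clip(
        rng.normal(mu_h, config.height_sd), config.height_range[0], config.height_range[1]
    )

    never = rng.random(n) < config.stratum_mix
    pack_years = np.zeros(n)
    n_ever = int((~never).sum())
    pack_years[~never] = config.pack_years_offset + rng.gamma(
        config.pack_years_shape, config.pack_years_scale, size=n_ever
    )
    current = np.zeros(n, dtype=bool)
    current[~never] = rng.random(n_ever) < config.current_smoker_fraction
    asthma = rng.random(n) < config.asthma_fraction

    geno, snp_info = simulate_genotypes(config)

    # Standardized liability.  Planted log-odds are converted to liability
    # shifts with the local probit→logit slope at the baseline LLN threshold,
    # phi(x0) / (Phi(x0)(1−Phi(x0))) with x0 = z_0.05 / sigma, so that a
    # logistic regression on case status recovers approximately the planted
    # per-allele log-odds (the mid-range constant 1.702 under-scales at
    # case rates far from 50 %).
    sigma = config.spirometry_noise
    x0 = stats.norm.ppf(0.05) / sigma
    scale = stats.norm.pdf(x0) / (stats.norm.cdf(x0) * stats.norm.sf(x0))
    eps = rng.normal(0.0, 1.0, size=n)
    for causal in config.causal_snps:
        if set(causal.affected_definitions) != set(DEFINITIONS):
            continue  # definition-specific SNPs act via plant_label_effects
        g = np.maximum(geno[:, causal.snp_index], 0).astype(float)  # missing → 0 dose
        eps = eps - g * causal.log_odds_per_allele / scale
    eps = eps - pack_years * config.pack_years_log_odds / scale
    z = sigma * eps

    ratio = reference.quantile(sex, age, height, z)
    ratio = np.clip(ratio, 25.0, 99.5)

    fvc = _simulate_fvc(rng, sex, age, height)
    fev1 = ratio / 100.0 * fvc

    subjects = pd.DataFrame(
        {
            "id": [f"S{i + 1:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "smoking_status": np.where(never, "never", "ever"),
            "pack_years": pack_years,
            "current_smoker": current,
            "fev1": fev1,
            "fvc": fvc,
            "asthma": asthma,
        }
    )
    return Cohort(subjects=subjects, genotypes=geno, snp_info=snp_info)


def plant_label_effects(labels: pd.DataFrame, cohort: Cohort, config: SimConfig) -> pd.DataFrame:
    """Apply definition-specific causal effects as a label perturbation.

    For each causal SNP whose ``affected_definitions`` is a proper subset of
    the two definitions, the targeted definition's case probability is raised
    multiplicatively: a control carrying ``g`` risk alleles becomes a case
    with probability ``(p0·exp(g·β) − p0)/(1 − p0)`` (clipped), which gives a
    marginal case rate of approximately ``p0·exp(g·β)`` while leaving the
    other definition's labels — and hence the shared-latent correlation —
    untouched.  Negative β flips cases to controls symmetrically.
    """
    out = labels.copy()
    rng = _rng(config.seed, 3)
    for causal in config.causal_snps:
        targets = set(causal.affected_definitions)
        if targets == set(DEFINITIONS):
            continue
        g = np.maximum(cohort.genotypes[:, causal.snp_index], 0).astype(float)
        for definition in targets:
            flags = out[definition].to_numpy(dtype=bool)
            valid = out["valid"].to_numpy(dtype=bool)
            p0 = flags[valid].mean()
            if not 0 < p0 < 1:
                continue
            target_p = np.clip(p0 * np.exp(g * causal.log_odds_per_allele), 0.0, 1.0)
            u = rng.random(len(out))
            if causal.log_odds_per_allele >= 0:
                p_flip = np.clip((target_p - p0) / (1.0 - p0), 0.0, 1.0)
                flags = flags | (valid & ~flags & (u < p_flip))
            else:
                p_flip = np.clip((p0 - target_p) / p0, 0.0, 1.0)
                flags = flags & ~(valid & flags & (u < p_flip))
            out[definition] = flags
    return out


def simulate_expression(
    cohort: Cohort,
    eqtl_effects: Sequence[tuple[int, str, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    n_null_probes: int = 20,
    cis_offset: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic lung-tissue expression with planted cis-eQTL effects.

    ``eqtl_effects`` lists (snp_index, probe_id, slope); each listed probe is
    annotated ``cis_offset`` bp downstream of its SNP.  ``n_null_probes``
    additional unassociated probes are scattered genome-wide.  Expression is
    intercept + slope·allele_count + small age and sex effects + Normal noise.

    Returns (expression, probe_annotation); expression is probes × subjects,
    annotation has columns probe_id, chromosome, position.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng([seed, 4])
    n = cohort.n_subjects
    age = cohort.subjects["age"].to_numpy(dtype=float)
    male = (cohort.subjects["sex"].to_numpy() == "male").astype(float)

    rows, ann = [], []
    for snp_index, probe_id, slope in eqtl_effects:
        if not 0 <= snp_index < cohort.n_snps:
            raise IndexError(f"snp_index {snp_index} out of range")
        g = np.maximum(cohort.genotypes[:, snp_index], 0).astype(float)
        expr = (
            8.0
            + slope * g
            + 0.005 * (age - age.mean())
            + 0.1 * male
            + rng.normal(0.0, noise_sd, size=n)
        )
        rows.append(pd.Series(expr, name=probe_id))
        snp = cohort.snp_info.iloc[snp_index]
        ann.append((probe_id, int(snp["chromosome"]), int(snp["position"]) + cis_offset))
    for k in range(n_null_probes):
        probe_id = f"null_probe_{k + 1:04d}"
        expr = 8.0 + rng.normal(0.0, noise_sd, size=n)
        rows.append(pd.Series(expr, name=probe_id))
        ann.append((probe_id, int(rng.integers(1, 23)), int(rng.integers(1, 200_000_000))))

    expression = pd.DataFrame(rows)
    expression.columns = cohort.subjects["id"].to_numpy()
    annotation = pd.DataFrame(ann, columns=["probe_id", "chromosome", "position"])
    return expression, annotation
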