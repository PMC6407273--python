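"""End-to-end pipeline driver.

A run takes a configuration (simulated or file-based inputs), produces a run
directory with obstruction labels, the QC report, the four
definition × stratum scans, overlap/agreement reports, both resampling
simulations, validation meta-analysis with interaction tests, a cis-eQTL
scan, and a provenance manifest.  Everything is deterministic given the
configuration seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .cohort import CausalSnp, SimConfig, plant_label_effects, simulate_cohort, simulate_expression
from .gwas import ScanSpec, interaction_scan, run_scan
from .meta import CohortEstimate, cis_eqtl_scan, fixed_effects_meta, replication_call
from .overlap import (DEFAULT_THRESHOLDS, agreement, bonferroni_threshold,
                      cross_stratum_overlap, threshold_overlap)
from .qc import QcThresholds, apply_qc
from .reference import (DEFINITIONS, STRATA, classify_obstruction, concordance_stats,
                        cross_classification, default_reference)
from .resampling import expand_cohort, null_overlap_experiment

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("spirogwas")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = SimConfig()
    qc: QcThresholds = QcThresholds()
    overlap_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    add_bonferroni_threshold: bool = True
    expansion_factors: tuple[int, ...] = (2, 4)
    run_expansion: bool = True
    null_overlap_replicates: int = 10
    null_overlap_thresholds: tuple[float, ...] = (1e-4, 1e-3)
    null_overlap_stratum: str = "never"
    run_null_overlap: bool = True
    candidate_threshold: float = 1e-4
    min_candidates: int = 2
    n_validation_cohorts: int = 2
    validation_n_subjects: int = 1500
    run_validation: bool = True
    run_eqtl: bool = True
    eqtl_noise_sd: float = 1.0
    eqtl_slope: float = 0.4
    lms_table: str | None = None

    def __post_init__(self):
        if len(self.overlap_thresholds) == 0:
            raise ValueError("overlap_thresholds must be non-empty")
        t = sorted(self.overlap_thresholds, reverse=True)
        if len(set(t)) != len(t):
            raise ValueError("overlap_thresholds must be distinct")

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            sim = dict(d["sim"])
            causal = [
                CausalSnp(c["snp_index"], c["log_odds_per_allele"],
                          frozenset(c.get("affected_definitions", DEFINITIONS)))
                for c in sim.pop("causal_snps", [])
            ]
            for key in ("maf_range", "age_range", "height_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(causal_snps=tuple(causal), **sim)
        if "qc" in d:
            d["qc"] = QcThresholds(**d["qc"])
        for key in ("overlap_thresholds", "expansion_factors", "null_overlap_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return PipelineConfig(**d)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _pick_candidates(scan70, scanlln, threshold: float, min_candidates: int) -> list[str]:
    """Top overlapping SNPs between the two definitions of one stratum:
    p < threshold in both scans; padded to ``min_candidates`` by the best
    max-of-both-p rank so downstream validation always has work to do."""
    merged = scan70.results.set_index("snp_id")[["p"]].join(
        scanlln.results.set_index("snp_id")[["p"]], lsuffix="_70", rsuffix="_lln"
    ).dropna()
    both = merged[(merged["p_70"] < threshold) & (merged["p_lln"] < threshold)]
    cand = list(both.index)
    if len(cand) < min_candidates:
        worst = merged[["p_70", "p_lln"]].max(axis=1).sort_values()
        for snp in worst.index:
            if snp not in cand:
                cand.append(snp)
            if len(cand) >= min_candidates:
                break
    return cand


def _overlap_rows(reports, pair_name):
    rows = []
    for r in reports:
        rows.append({
            "pair": pair_name,
            "threshold": r.threshold,
            "n_hits_a": r.n_hits_a,
            "n_hits_b": r.n_hits_b,
            "n_overlap": r.n_overlap,
            "n_union": r.n_union,
            "pct_overlap_of_union": (np.nan if r.pct_overlap_of_union is None
                                     else r.pct_overlap_of_union),
        })
    return rows


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every configured stage; returns a summary dict mirroring the
    manifest written to ``outdir/manifest.json``."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}}
    manifest["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "spirogwas": _package_version(),
    }

    def stage(name, **counts):
        log.info("stage %-16s %s  (%.1fs)", name, counts, time.monotonic() - t0)
        manifest["stages"][name] = counts

    reference = (sio.read_lms_table(config.lms_table) if config.lms_table
                 else default_reference())
    cohort = simulate_cohort(config.sim, reference)
    stage("simulate", n_subjects=cohort.n_subjects, n_snps=cohort.n_snps)

    labels = classify_obstruction(cohort, reference)
    labels = plant_label_effects(labels, cohort, config.sim)
    sio.write_labels(labels, outdir / "labels.tsv")
    concordance = {}
    for stratum in STRATA:
        cc = cross_classification(labels, stratum)
        st = concordance_stats(cc)
        concordance[stratum] = {
            "n": cc.n, "n70": cc.n70, "nlln": cc.nlln, "nboth": cc.nboth,
            "n_union": cc.n_union, "n_discordant": cc.n_discordant,
            "pct_concordant": st.pct_concordant,
            "pct_discordant_among_union": st.pct_discordant_among_union,
            "pct_overlap_cases": st.pct_overlap_cases,
        }
    (outdir / "concordance.json").write_text(json.dumps(concordance, indent=2, sort_keys=True))
    stage("classify", **{s: concordance[s]["n"] for s in STRATA})

    cohort_qc, qc_report = apply_qc(cohort, config.qc)
    qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    stage("qc", n_snps_in=cohort.n_snps, n_snps_pass=cohort_qc.n_snps)

    thresholds = list(config.overlap_thresholds)
    if config.add_bonferroni_threshold:
        thresholds.append(bonferroni_threshold(0.05, cohort_qc.n_snps))
    scans = {}
    for definition in DEFINITIONS:
        for stratum in STRATA:
            spec = ScanSpec(definition, stratum)
            summary = run_scan(cohort_qc, labels, spec)
            scans[(definition, stratum)] = summary
            sio.write_summary_stats(summary, outdir / f"scan_{definition}_{stratum}.tsv")
    stage("scan", **{f"lambda_{d}_{s}": round(scans[(d, s)].lambda_gc, 4)
                     for d in DEFINITIONS for s in STRATA})

    overlap_rows, agreement_rows = [], []
    for stratum in STRATA:
        pair = f"{stratum}:fixed70_vs_lln"
        reps = threshold_overlap(scans[("fixed70", stratum)], scans[("lln", stratum)], thresholds)
        overlap_rows += _overlap_rows(reps, pair)
        ag = agreement(scans[("fixed70", stratum)], scans[("lln", stratum)])
        agreement_rows.append({"pair": pair, "r_pvalue": ag.r_pvalue,
                               "r_or": ag.r_or, "n_snps": ag.n_snps})
    cross = cross_stratum_overlap(scans, thresholds)
    for (ka, kb), rep in cross.items():
        pair = f"{ka[0]}_{ka[1]}__vs__{kb[0]}_{kb[1]}"
        overlap_rows += _overlap_rows(rep["overlap"], pair)
        ag = rep["agreement"]
        agreement_rows.append({"pair": pair, "r_pvalue": ag.r_pvalue,
                               "r_or": ag.r_or, "n_snps": ag.n_snps})
    pd.DataFrame(overlap_rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    pd.DataFrame(agreement_rows).to_csv(outdir / "agreement.tsv", sep="\t", index=False)
    venn = {
        row["pair"] + f"@{row['threshold']:g}": {
            "a_only": row["n_hits_a"] - row["n_overlap"],
            "b_only": row["n_hits_b"] - row["n_overlap"],
            "both": row["n_overlap"],
        }
        for row in overlap_rows
    }
    (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
    stage("overlap", n_pairs=len(agreement_rows), n_thresholds=len(thresholds))

    if config.run_expansion:
        exp_rows = []
        for k in config.expansion_factors:
            big_cohort, big_labels = expand_cohort(cohort_qc, labels, k)
            s70 = run_scan(big_cohort, big_labels, ScanSpec("fixed70", "never"))
            slln = run_scan(big_cohort, big_labels, ScanSpec("lln", "never"))
            for rep in threshold_overlap(s70, slln, thresholds):
                exp_rows.append({
                    "k": k, "n_subjects": big_cohort.n_subjects,
                    "threshold": rep.threshold, "n_hits_70": rep.n_hits_a,
                    "n_hits_lln": rep.n_hits_b, "n_overlap": rep.n_overlap,
                    "pct_overlap_of_union": (np.nan if rep.pct_overlap_of_union is None
                                             else rep.pct_overlap_of_union),
                })
        pd.DataFrame(exp_rows).to_csv(outdir / "expansion.tsv", sep="\t", index=False)
        stage("expansion", factors=list(config.expansion_factors))

    if config.run_null_overlap:
        dists = null_overlap_experiment(
            cohort_qc, labels, stratum=config.null_overlap_stratum,
            replicates=config.null_overlap_replicates,
            thresholds=config.null_overlap_thresholds, seed=config.sim.seed,
        )
        payload = {
            f"{t:g}": {"replicates": d.replicates, "min": d.min, "max": d.max,
                       "mean": d.mean, "overlap_pcts": list(d.overlap_pcts)}
            for t, d in dists.items()
        }
        (outdir / "null_overlap.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        stage("null_overlap", replicates=config.null_overlap_replicates)

    candidates: list[str] = []
    if config.run_validation:
        candidates = _pick_candidates(
            scans[("fixed70", "never")], scans[("lln", "never")],
            config.candidate_threshold, config.min_candidates,
        )
        cand_idx = [int(cohort_qc.snp_info.index[cohort_qc.snp_info["snp_id"] == s][0])
                    for s in candidates]
        meta_rows = []
        val_cohorts = []
        for c in range(config.n_validation_cohorts):
            vc_sim = dataclasses.replace(
                config.sim,
                n_subjects=config.validation_n_subjects,
                seed=config.sim.seed + 1001 + c,
            )
            vc = simulate_cohort(vc_sim, reference)
            vl = classify_obstruction(vc, reference)
            vl = plant_label_effects(vl, vc, vc_sim)
            val_cohorts.append((f"validation_{c + 1}", vc, vl))
        for definition in DEFINITIONS:
            for snp, j in zip(candidates, cand_idx):
                estimates = []
                for name, vc, vl in val_cohorts:
                    sub = vc.subset_snps(np.array([j]))
                    res = run_scan(sub, vl, ScanSpec(definition, "never")).results.iloc[0]
                    if res["converged"]:
                        estimates.append(CohortEstimate(name, snp, res["beta"],
                                                        res["se"], int(res["n_used"])))
                if not estimates:
                    continue
                mr = fixed_effects_meta(estimates)
                call = replication_call(mr, n_candidates=len(candidates))
                meta_rows.append({
                    "snp_id": snp, "definition": definition,
                    "beta_meta": mr.beta_meta, "se_meta": mr.se_meta,
                    "p_meta": mr.p_meta, "q": mr.q_stat, "i2": mr.i2,
                    "direction": mr.direction,
                    "replicated": call["replicated"],
                    "replication_threshold": call["threshold"],
                })
        pd.DataFrame(meta_rows).to_csv(outdir / "meta.tsv", sep="\t", index=False)
        inter = []
        for definition in DEFINITIONS:
            df = interaction_scan(cohort_qc, labels, definition, cand_idx)
            df.insert(1, "definition", definition)
            inter.append(df)
        pd.concat(inter, ignore_index=True).to_csv(outdir / "interaction.tsv",
                                                   sep="\t", index=False)
        stage("validation", n_candidates=len(candidates),
              n_cohorts=config.n_validation_cohorts)

    if config.run_eqtl and candidates:
        cand_idx = [int(cohort_qc.snp_info.index[cohort_qc.snp_info["snp_id"] == s][0])
                    for s in candidates]
        effects = [(cand_idx[0], f"probe_{candidates[0]}", config.eqtl_slope)]
        expression, annot = simulate_expression(
            cohort_qc, effects, noise_sd=config.eqtl_noise_sd, seed=config.sim.seed
        )
        covs = pd.DataFrame({
            "disease": labels["fixed70"].to_numpy(dtype=float),
            "age": cohort_qc.subjects["age"],
            "sex": cohort_qc.subjects["sex"],
            "smoking": (cohort_qc.subjects["pack_years"] > 0).astype(float),
        })
        eqtl_frames = []
        for snp, j in zip(candidates, cand_idx):
            info = cohort_qc.snp_info.iloc[j]
            eqtl_frames.append(cis_eqtl_scan(
                snp, int(info["chromosome"]), int(info["position"]),
                cohort_qc.genotypes[:, j], expression, annot, covariates=covs,
            ))
        nonempty = [f for f in eqtl_frames if not f.empty]
        eqtl_all = (pd.concat(nonempty, ignore_index=True) if nonempty
                    else eqtl_frames[0])
        eqtl_all.to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
        stage("eqtl", n_snps=len(candidates), n_probes=len(annot))

    manifest["n_snps_post_qc"] = cohort_qc.n_snps
    manifest["concordance"] = concordance
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete in %.1fs", time.monotonic() - t0)
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("spirogwas")
    except PackageNotFoundError:
        return "unknown"


def demo_config(seed: int = 1) -> PipelineConfig:
    """The bundled demonstration configuration: 2,000 subjects × 5,000 SNPs
    with two planted shared-effect SNPs, every stage enabled at a scale that
    completes in minutes on one CPU."""
    from importlib.resources import files

    import yaml

    d = yaml.safe_load((files("spirogwas") / "data" / "demo.yaml").read_text())
    d["sim"]["seed"] = seed
    return PipelineConfig.from_dict(d)
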