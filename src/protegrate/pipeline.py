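"""End-to-end pipeline: simulate/load -> genomics -> quant -> ledgers ->
scores -> clustering -> survival, with plain-file handoff between stages.

Every output file carries a header comment with the config hash and
seed, so deleting intermediates and re-running reproduces them exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from protegrate import cis_trans, cnv_genomics, consensus_clustering, enrichment_scoring, io, plots
from protegrate import ksea as ksea_mod
from protegrate import survival_stats, synthetic_cohort

log = logging.getLogger("protegrate")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and toggles, with the study defaults."""

    seed: int = 0
    out_dir: str = "protegrate_out"
    # synthetic cohort
    n_samples: int = 200
    n_genes: int = 2000
    noise_sd: float = 0.5
    # stage toggles
    run_cnv: bool = True
    run_signatures: bool = True
    run_cistrans: bool = True
    run_scores: bool = True
    run_ksea: bool = True
    run_cluster: bool = True
    run_survival: bool = True
    # thresholds
    amp_del_cutoff: float = 1.0
    coding_mb: float = 31.6
    n_signatures: int = 2
    phospho_min_prob: float = 0.75
    fot_scale: float = 1e6
    impute_value: float = 1e-5
    cis_p_threshold: float = 0.05
    fc_threshold: float = 2.0
    de_p_threshold: float = 0.05
    ssgsea_alpha: float = 0.25
    ssgsea_min_size: int = 10
    ksea_min_substrates: int = 3
    cluster_k_min: int = 2
    cluster_k_max: int = 5
    cluster_reps: int = 200
    cluster_p_item: float = 0.8
    cluster_p_feature: float = 1.0
    cluster_top_var_fraction: float = 0.5
    cutpoint_minprop: float = 0.1

    def validate(self) -> None:
        if not (0 < self.cluster_p_item <= 1) or not (0 < self.cluster_p_feature <= 1):
            raise ValueError("pItem and pFeature must lie in (0, 1]")
        if self.amp_del_cutoff <= 0:
            raise ValueError("amp_del_cutoff must be positive")
        if not (0 <= self.cutpoint_minprop < 0.5):
            raise ValueError("cutpoint_minprop must lie in [0, 0.5)")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys, and materialize defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage on a synthetic cohort; returns result paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"protegrate config={cfg.hash()} seed={cfg.seed}"
    results: dict = {"config_hash": cfg.hash()}

    spec = synthetic_cohort.default_cohort_spec(
        n_samples=cfg.n_samples, n_genes=cfg.n_genes, seed=cfg.seed, noise_sd=cfg.noise_sd
    )
    cohort = synthetic_cohort.generate_cohort(spec)
    log.info("simulate: %d samples, %d genes, %d mutations",
             cfg.n_samples, cfg.n_genes, len(cohort.mutations))
    synthetic_cohort.write_cohort(out / "cohort", cohort, overwrite=True)
    results["cohort_dir"] = str(out / "cohort")

    cn = cnv_genomics.gene_copy_number(cohort.segments, cohort.gene_model)
    if cfg.run_cnv:
        arms = cnv_genomics.arm_score(cohort.segments, cohort.gene_model)
        calls = cnv_genomics.call_amp_del(arms, cutoff=cfg.amp_del_cutoff)
        tmb = cnv_genomics.tmb(cohort.mutations, cfg.coding_mb,
                               samples=cohort.mrna.samples)
        io.write_matrix_tsv(out / "arm_scores.tsv", arms, header)
        io.write_matrix_tsv(out / "arm_calls.tsv", calls, header)
        io.write_matrix_tsv(out / "gene_copy_number.tsv", cn.data, header)
        tmb.rename("tmb").to_frame().to_csv(out / "tmb.tsv", sep="\t")
        results["tmb_mean"] = float(tmb.mean())
        log.info("cnv: %d arms, mean TMB %.2f", arms.shape[0], tmb.mean())

    if cfg.run_signatures:
        contexts = cnv_genomics.context_matrix(cohort.mutations)
        fit = cnv_genomics.extract_signatures(
            contexts, k=cfg.n_signatures,
            reference=synthetic_cohort.reference_signatures(), seed=cfg.seed,
        )
        io.write_matrix_tsv(out / "signature_profiles.tsv", fit.profiles, header)
        io.write_matrix_tsv(out / "signature_exposures.tsv", fit.exposures, header)
        results["signature_matches"] = fit.matched
        log.info("signatures: matched %s", fit.matched)

    ledgers = {}
    if cfg.run_cistrans:
        for layer, matrix in (("mrna", cohort.mrna), ("protein", cohort.protein)):
            ledgers[layer] = cis_trans.correlate_layers(cn, matrix, layer=layer, mode="cis_only")
        phospho_prot = cis_trans.collapse_phosphosites(cohort.phospho)
        ledgers["phospho"] = cis_trans.correlate_layers(
            cn, phospho_prot, layer="phospho", mode="cis_only")
        for layer, led in ledgers.items():
            led.to_csv(out / f"cis_ledger_{layer}.tsv", sep="\t", index=False)
        overlap = cis_trans.cis_overlap(ledgers, p_threshold=cfg.cis_p_threshold)
        (out / "cis_overlap.json").write_text(json.dumps(overlap, indent=2))
        results["cis_region_counts"] = overlap["region_counts"]
        log.info("cistrans: region counts %s", overlap["region_counts"])

    if cfg.run_scores:
        scores = enrichment_scoring.ssgsea(
            cohort.protein, cohort.gene_sets,
            alpha=cfg.ssgsea_alpha, min_size=cfg.ssgsea_min_size,
        )
        io.write_matrix_tsv(out / "pathway_scores.tsv", scores, header)
        results["n_score_sets"] = int(scores.shape[0])

    if cfg.run_ksea:
        activity = ksea_mod.ksea_scores(
            cohort.phospho, cohort.ks_map, min_substrates=cfg.ksea_min_substrates)
        io.write_matrix_tsv(out / "kinase_activity.tsv", activity.z, header)
        results["n_kinases"] = int(activity.z.shape[0])

    labels = None
    if cfg.run_cluster:
        res = consensus_clustering.consensus_cluster(
            cohort.protein.data,
            k_range=range(cfg.cluster_k_min, cfg.cluster_k_max + 1),
            reps=cfg.cluster_reps, p_item=cfg.cluster_p_item,
            p_feature=cfg.cluster_p_feature,
            top_var_fraction=cfg.cluster_top_var_fraction, seed=cfg.seed,
        )
        labels = res.labels[res.chosen_k]
        labels.rename("cluster").to_csv(out / "cluster_labels.tsv", sep="\t")
        io.write_matrix_tsv(out / f"consensus_k{res.chosen_k}.tsv",
                            res.consensus[res.chosen_k], header)
        plots.plot_consensus_cdf(res, out / "consensus_cdf.png")
        plots.plot_consensus_matrix(res, res.chosen_k,
                                    out / f"consensus_k{res.chosen_k}.png")
        results["chosen_k"] = res.chosen_k
        results["silhouette"] = res.silhouette
        log.info("cluster: chose k=%d (silhouette %s)", res.chosen_k, res.silhouette)

    if cfg.run_survival and labels is not None:
        surv = cohort.survival.copy()
        surv["group"] = labels.loc[surv["sample"]].to_numpy()
        curves, chi2, p = survival_stats.km_logrank(surv, "group")
        plots.plot_km(curves, out / "km_clusters.png")
        results["cluster_logrank_p"] = p
        pd.DataFrame([{"test": "logrank_clusters", "chi2": chi2, "p": p}]).to_csv(
            out / "survival_tests.tsv", sep="\t", index=False)
        log.info("survival: cluster log-rank p=%.3g", p)

    report = [f"# protegrate pipeline report", "",
              f"- config hash: {cfg.hash()}", f"- seed: {cfg.seed}",
              f"- samples: {cfg.n_samples}, genes: {cfg.n_genes}", ""]
    for key, val in results.items():
        report.append(f"- {key}: {val}")
    (out / "report.md").write_text("\n".join(report) + "\n")
    results["report"] = str(out / "report.md")
    return results
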