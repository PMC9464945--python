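"""End-to-end orchestration: simulate -> prep -> EPM -> features -> cluster
-> characterize -> SPGI, with a resolved-config manifest per run.

All randomness funnels through one master seed: each stage derives its own
child seed from ``numpy.random.SeedSequence(master_seed).spawn``, so a run is
fully reproducible (identical config => byte-identical outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as epio
from . import synthetic
from .characterization import characteristic_groups, group_edges
from .clustering import consensus_cluster, igp, select_k, zscore_by_edge
from .epm import build_epm, perturbation_amplitude
from .feature_edges import kw_edge_scan, select_feature_edges
from .network import GeneInteractionNetwork
from .preprocess import align_cohorts, filter_low_expressed_genes
from .spgi import (
    cox_screen,
    evaluate_prognosis,
    lasso_cox_fit,
    log2p,
    pairwise_degs,
    recurrent_degs,
    spgi_score,
)

log = logging.getLogger("epmkit")

STAGES = ["simulate", "prep", "epm", "features", "cluster", "characterize", "spgi"]


@dataclass
class RunConfig:
    """Resolved parameters of a full pipeline run (one master seed)."""

    out_dir: str = "epmkit_run"
    master_seed: int = 0
    # simulate
    n_genes: int = 300
    attach_m: int = 2
    n_normal: int = 50
    k_clusters: int = 4
    n_per_cluster: int = 20
    edges_per_cluster: int = 50
    flip_strength: float = 1.0
    noise_sd: float = 0.3
    n_prognostic: int = 5
    n_decoy: int = 20
    censor_rate: float = 0.3
    # prep
    zero_fraction_threshold: float = 0.7
    # features
    top_k_test: int = 60000
    top_k_sd: int = 60000
    # cluster
    k_min: int = 2
    k_max: int = 6
    reps: int = 250
    sample_fraction: float = 0.8
    min_rel_increase: float = 0.05
    # characterize
    n_groups: int = 20
    min_group_size: int = 10
    mean_threshold: float = 0.5
    frac_threshold: float = 0.7
    # spgi
    deg_fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    deg_min_occurrences: int = 4
    cox_p_threshold: float = 0.05
    n_folds: int = 10

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        stage: int(ss.generate_state(1)[0] % (2**31))
        for stage, ss in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on a simulated dataset and write all artifacts.

    Returns the run directory. Each stage's outputs are plain text (TSV/JSON);
    the manifest records the resolved config, per-stage seeds, and a config
    hash, so reruns with the same config reproduce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "stages": [],
    }
    config.to_yaml(out / "config.yaml")

    def stage_done(name: str, **info) -> None:
        log.info("stage %s done: %s", name, info)
        manifest["stages"].append({"name": name, **info})

    try:
        # --- simulate -----------------------------------------------------
        net = synthetic.generate_network(config.n_genes, config.attach_m, seed=seeds["simulate"])
        baseline = synthetic.gene_baseline(net, seed=seeds["simulate"])
        normal = synthetic.generate_normal_cohort(
            net, config.n_normal, noise_sd=config.noise_sd, seed=seeds["simulate"] + 1,
            baseline=baseline,
        )
        tumor, truth = synthetic.generate_tumor_cohort(
            net, baseline,
            k_clusters=config.k_clusters, n_per_cluster=config.n_per_cluster,
            edges_per_cluster=config.edges_per_cluster,
            flip_strength=config.flip_strength, noise_sd=config.noise_sd,
            seed=seeds["simulate"] + 2,
        )
        tumor = synthetic.plant_prognostic_genes(
            tumor, truth, n_prognostic=config.n_prognostic, n_decoy=config.n_decoy,
            seed=seeds["simulate"] + 3,
        )
        survival = synthetic.generate_survival(
            truth, tumor, censor_rate=config.censor_rate, seed=seeds["simulate"] + 4
        )
        epio.write_edge_list(net.edges, out / "network.tsv")
        epio.write_expression(normal, out / "normal_expression.tsv")
        epio.write_expression(tumor, out / "tumor_expression.tsv")
        survival.to_csv(out / "survival.tsv", sep="\t", index_label="sample_id")
        epio.write_json(
            {
                "true_cluster": truth.true_cluster.to_dict(),
                "perturbed_edges": {
                    str(c): [f"{i}|{j}" for i, j in e] for c, e in truth.perturbed_edges.items()
                },
                "prognostic_genes": truth.prognostic_genes,
                "params": truth.params,
            },
            out / "truth.json",
        )
        stage_done("simulate", n_edges=net.n_edges, n_tumor=tumor.shape[1])

        # --- prep ---------------------------------------------------------
        normal = filter_low_expressed_genes(normal, config.zero_fraction_threshold)
        tumor = filter_low_expressed_genes(tumor, config.zero_fraction_threshold)
        (tumor, normal), net = align_cohorts([tumor, normal], net)
        stage_done("prep", n_genes=tumor.shape[0], n_edges=net.n_edges)

        # --- epm ----------------------------------------------------------
        epm_tumor = build_epm(tumor, normal, net)
        epm_normal = build_epm(normal, normal, net)
        epio.write_epm(epm_tumor, out / "epm_tumor.tsv")
        amp_t = perturbation_amplitude(epm_tumor).per_sample_mean
        amp_n = perturbation_amplitude(epm_normal).per_sample_mean
        pd.DataFrame({"amplitude": pd.concat([amp_t, amp_n])}).to_csv(
            out / "amplitude.tsv", sep="\t", index_label="sample_id"
        )
        stage_done("epm", mean_amp_tumor=float(amp_t.mean()), mean_amp_normal=float(amp_n.mean()))

        # --- features -----------------------------------------------------
        kw = kw_edge_scan(epm_tumor, epm_normal)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = select_feature_edges(kw, epm_tumor, config.top_k_test, config.top_k_sd)
        feats.table.to_csv(out / "feature_edges.tsv", sep="\t", index_label="edge")
        stage_done("features", n_selected=len(feats.edge_ids), n_genes=len(feats.genes))

        # --- cluster ------------------------------------------------------
        feat_matrix = epm_tumor.loc[feats.edge_ids]
        cons = consensus_cluster(
            feat_matrix, k_range=range(config.k_min, config.k_max + 1),
            reps=config.reps, sample_fraction=config.sample_fraction,
            seed=seeds["cluster"],
        )
        chosen_k = select_k(cons, config.min_rel_increase)
        labels = cons.labels[chosen_k]
        labels.to_csv(out / "cluster_labels.tsv", sep="\t", index_label="sample_id")
        epio.write_json(
            {"cdf_area": cons.cdf_area, "delta_area": cons.delta_area, "chosen_k": chosen_k},
            out / "consensus_report.json",
        )
        stage_done("cluster", chosen_k=chosen_k,
                   sizes=labels.value_counts().sort_index().tolist())

        # --- characterize -------------------------------------------------
        zmat = zscore_by_edge(feat_matrix)
        grouping = group_edges(
            zmat, n_groups=min(config.n_groups, zmat.shape[0]), min_size=config.min_group_size
        )
        chars = characteristic_groups(
            grouping, zmat, labels, config.mean_threshold, config.frac_threshold
        )
        chars.fractions.to_csv(out / "characteristic_fractions.tsv", sep="\t")
        epio.write_json(
            {str(c): sorted(g) for c, g in chars.genes_per_cluster.items()},
            out / "cluster_genes.json",
        )
        stage_done("characterize", retained_groups=len(grouping.retained_groups))

        # --- spgi ---------------------------------------------------------
        lx = log2p(tumor)
        degs = pairwise_degs(lx, labels, config.deg_fdr, config.min_abs_log2fc)
        recurrent = recurrent_degs(degs, config.deg_min_occurrences)
        screen = cox_screen(lx, survival, recurrent, config.cox_p_threshold)
        prognostic = sorted(screen.index[screen["prognostic"]]) if len(screen) else []
        model = lasso_cox_fit(lx, survival, prognostic, config.n_folds, seed=seeds["spgi"])
        scored = spgi_score(model, lx)
        report = evaluate_prognosis(scored["score"], scored["high_risk"], survival)
        epio.write_json(model.to_dict(), out / "spgi_model.json")
        scored.to_csv(out / "spgi_scores.tsv", sep="\t", index_label="sample_id")
        epio.write_json(report, out / "spgi_evaluation.json")
        stage_done("spgi", n_recurrent=len(recurrent), n_prognostic=len(prognostic),
                   n_selected=len(model.genes))
    except Exception as err:
        failed = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        epio.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline aborted at stage '{failed}': {err}") from err

    epio.write_json(manifest, out / "manifest.json")
    return out
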