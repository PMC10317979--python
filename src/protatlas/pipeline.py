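"""End-to-end orchestration: configuration and the ``full-run`` pipeline.

A run simulates an atlas (or loads one), then chains every analysis stage —
differential abundance, markers, composition, regional dynamics, temporal
events, trend clustering, enrichment dynamics, cross-species conservation
and RNA/protein concordance — writing one TSV per result plus a manifest
with the configuration hash and the checksum of every output.  All
randomness flows from one root seed, so a repeated run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as paio
from .composition import adjacent_stage_trend_test, composition_percent, trend_flags
from .concordance import classify_six_types, type_percentages
from .core import STAGES, AbundanceMatrix
from .cross_species import classify_conservation, correlation_distribution, family_correlations, ortholog_correlations
from .differential import dep_counts_by_group, dep_region_vs_rest, dep_stage_vs_rest, dep_summary
from .enrichment import enrichment_by_stage, overlap_curve
from .markers import find_markers, top_marker_matrix
from .regional import cb_distance, inter_regional_curve, pca_scores, stage_correlation
from .simulate import SimConfig, simulate_atlas, simulate_ortholog_panel, simulate_rna_protein_pairs
from .temporal import call_new_proteins, fuzzy_cmeans_trends, rate_of_change, set_trajectory


@dataclass
class RunConfig:
    """Structured configuration of a full run; unknown keys are rejected."""

    seed: int = 0
    alpha: float = 0.05
    auc_threshold: float = 0.7
    fc_threshold: float = 1.0
    fc_large: float = 2.0
    log2_fc: bool = False
    welch: bool = False
    exclude_region_for_stage_dep: str = "CB"
    overlap_q_threshold: float = 0.05
    include_same_region_pairs: bool = False
    n_clusters: int = 4
    fuzzifier: float = 2.0
    top_n_markers: int = 10
    top_k_families: int = 5
    n_orthologs: int = 300
    ortholog_noise_sd: float = 0.05
    n_rna_genes: int = 600
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            cfg.sim = SimConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["stage_regions"] = {k: list(v) for k, v in d["sim"]["stage_regions"].items()}
        return d


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def full_run(cfg: RunConfig, outdir) -> dict:
    """Execute every stage on a freshly simulated atlas; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(2**31, size=4)

    def fmt(df: pd.DataFrame) -> pd.DataFrame:
        return df.round(10)

    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(cfg.sim, seed=int(seeds[0]))
        sim = simulate_atlas(sim_cfg)
        m = sim.matrix
        paio.write_abundance(m, out / "lfq_matrix.tsv", out / "sample_meta.tsv")
        paio.write_table(sim.ledger, out / "truth_ledger.tsv", "simulate_atlas", "planted_roles")
        paio.write_annotation(sim.annotation, out / "annotation.tsv")
        paio.write_gmt(sim.gene_sets, out / "gene_sets.gmt")
        stages_present = [s for s in STAGES if s in set(m.meta["stage"])]

        stage = "dep"
        region_frames = [dep_region_vs_rest(m, s, cfg.alpha, equal_var=not cfg.welch)
                         for s in stages_present]
        region_deps = pd.concat(region_frames, ignore_index=True)
        stage_deps = dep_stage_vs_rest(m, exclude_region=cfg.exclude_region_for_stage_dep,
                                       alpha=cfg.alpha, equal_var=not cfg.welch)
        paio.write_table(fmt(region_deps[region_deps["dep"]]), out / "dep_region.tsv",
                         "dep_region_vs_rest", "log2_t_test")
        paio.write_table(fmt(stage_deps[stage_deps["dep"]]), out / "dep_stage.tsv",
                         "dep_stage_vs_rest", "log2_t_test")
        summary = dep_summary(stage_deps, region_deps)
        paio.write_table(pd.DataFrame([summary]), out / "dep_summary.tsv",
                         "dep_summary", "protein_counts")
        paio.write_table(dep_counts_by_group(region_deps), out / "dep_counts.tsv",
                         "dep_counts_by_group", "protein_counts")

        stage = "markers"
        stage_markers = find_markers(m.subset(m.samples(exclude_region="CB")), "stage",
                                     cfg.auc_threshold, cfg.fc_threshold, log2_fc=cfg.log2_fc)
        macro_markers = find_markers(m, "macro_region", cfg.auc_threshold, cfg.fc_threshold,
                                     log2_fc=cfg.log2_fc)
        paio.write_table(fmt(stage_markers), out / "markers_stage.tsv",
                         "find_markers", "auc_and_linear_fc")
        paio.write_table(fmt(macro_markers), out / "markers_macro.tsv",
                         "find_markers", "auc_and_linear_fc")
        top = top_marker_matrix(m, stage_markers, cfg.top_n_markers, by="stage")
        paio.write_table(fmt(top.reset_index(names="class")), out / "markers_top_matrix.tsv",
                         "top_marker_matrix", "mean_zscored_log2")

        stage = "composition"
        prof = composition_percent(m, sim.annotation, "localization")
        seg = adjacent_stage_trend_test(prof, m.meta, group_by="macro_region", alpha=cfg.alpha)
        paio.write_table(fmt(prof), out / "composition_localization.tsv",
                         "composition_percent", "percent_of_total_LFQ")
        paio.write_table(fmt(seg), out / "composition_trends.tsv",
                         "adjacent_stage_trend_test", "t_test_per_segment")
        paio.write_table(trend_flags(seg), out / "composition_flags.tsv",
                         "trend_flags", "boolean")

        stage = "dynamics"
        paio.write_table(fmt(inter_regional_curve(
            m, include_same_region=cfg.include_same_region_pairs)),
            out / "inter_regional.tsv", "inter_regional_difference", "mean_abs_log2_diff")
        cbd = pd.concat([cb_distance(m, s) for s in stages_present
                         if m.samples(stage=s, region="CB")], ignore_index=True)
        paio.write_table(fmt(cbd), out / "cb_distance.tsv", "cb_distance", "euclidean_log2")
        paio.write_table(fmt(stage_correlation(m)), out / "stage_correlation.tsv",
                         "stage_correlation", "pearson_r")
        scores, frac = pca_scores(m, n_components=2)
        scores = scores.copy()
        scores.insert(0, "sample_id", scores.index)
        paio.write_table(fmt(scores.reset_index(drop=True)), out / "pca_scores.tsv",
                         "pca_scores", f"scores_explained_var={frac.round(4).tolist()}")

        stage = "events"
        new_frames = []
        for s0, s1 in zip(stages_present, stages_present[1:]):
            calls = call_new_proteins(m, (s0, s1), macro_region="CTX",
                                      alpha=cfg.alpha, fc_threshold=cfg.fc_threshold)
            new_frames.append(calls[calls["status"] == "new"])
        paio.write_table(fmt(pd.concat(new_frames, ignore_index=True)),
                         out / "new_proteins.tsv", "call_new_proteins", "emergence_calls")
        rates = pd.concat([rate_of_change(m, (s0, s1), macro_region="CTX")
                           for s0, s1 in zip(stages_present, stages_present[1:])],
                          ignore_index=True)
        paio.write_table(fmt(rates), out / "rates.tsv", "rate_of_change", "log2_per_day")
        traj, traj_seg = set_trajectory(m, sim.gene_sets, sim.annotation, macro_region="CTX",
                                        alpha=cfg.alpha)
        paio.write_table(fmt(traj), out / "set_trajectories.tsv",
                         "set_trajectory", "summed_LFQ_mean_sd")
        paio.write_table(fmt(traj_seg), out / "set_trajectory_segments.tsv",
                         "set_trajectory", "t_test_per_segment")

        stage = "cluster"
        memb, centroids, history = fuzzy_cmeans_trends(
            m, c=cfg.n_clusters, fuzzifier=cfg.fuzzifier, seed=int(seeds[3]))
        memb = memb.copy()
        memb.insert(0, "protein_id", memb.index)
        paio.write_table(fmt(memb.reset_index(drop=True)), out / "fcm_memberships.tsv",
                         "fuzzy_cmeans_trends", "membership_fractions")
        paio.write_table(fmt(centroids.reset_index(names="cluster")),
                         out / "fcm_centroids.tsv", "fuzzy_cmeans_trends", "zscored_log2")

        stage = "enrich"
        marker_genes = {
            lab: {sim.annotation.gene_symbol[p]
                  for p in sub.loc[sub["marker"], "protein_id"]}
            for lab, sub in stage_markers.groupby("class", sort=False)
        }
        universe = {sim.annotation.gene_symbol[p]
                    for p in m.proteins[m.detected.any(axis=1)]}
        enr = enrichment_by_stage(marker_genes, sim.gene_sets, universe,
                                  cfg.overlap_q_threshold)
        enr_all = pd.concat([df.assign(stage=s).drop(columns="overlap_genes")
                             for s, df in enr.items()], ignore_index=True)
        paio.write_table(fmt(enr_all), out / "enrichment.tsv", "ora", "hypergeometric_BH")
        paio.write_table(fmt(overlap_curve(enr, stages_present)),
                         out / "enrichment_overlap.tsv", "overlap_curve",
                         "percent_overlap_both_rules")

        stage = "xspecies"
        panel, xledger, xann = simulate_ortholog_panel(
            cfg.n_orthologs, noise_sd=cfg.ortholog_noise_sd, seed=int(seeds[1]))
        paio.write_ortholog_panel(panel, out / "ortholog_panel.tsv")
        calls = classify_conservation(ortholog_correlations(panel))
        calls = calls.merge(xledger[["ortholog_id", "class"]].rename(
            columns={"class": "planted_class"}), on="ortholog_id")
        paio.write_table(fmt(calls), out / "conservation_calls.tsv",
                         "classify_conservation", "pearson_r_and_class")
        dist = correlation_distribution(calls)
        paio.write_table(fmt(dist["histogram"]), out / "correlation_histogram.tsv",
                         "correlation_distribution", "percent_per_bin")
        paio.write_table(fmt(dist["ks"]), out / "correlation_ks.tsv",
                         "correlation_distribution", "two_sample_KS")
        paio.write_table(fmt(family_correlations(panel, xann, cfg.top_k_families)),
                         out / "family_correlations.tsv", "family_correlations", "pearson_r")

        stage = "concordance"
        pairs, cledger = simulate_rna_protein_pairs(cfg.n_rna_genes, seed=int(seeds[2]))
        typed = classify_six_types(pairs, threshold=cfg.fc_large)
        typed = typed.merge(cledger, on="gene")
        paio.write_table(fmt(typed), out / "concordance_types.tsv",
                         "classify_six_types", "linear_fold_change")
        paio.write_table(fmt(type_percentages(typed, by=None)),
                         out / "concordance_percentages.tsv", "type_percentages", "percent")
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p.name for p in out.iterdir() if p.suffix in {".tsv", ".gmt"})
    manifest = {
        "seed": cfg.seed,
        "config_hash": _hash_config(cfg),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
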