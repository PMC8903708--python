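"""End-to-end orchestration of the discovery flow on synthetic data.

The pipeline reproduces the screening sequence: simulate (or load) an
expression cohort -> abundance filter -> differential expression (IgD vs
IgG) -> co-expression network (soft threshold, TOM, modules, eigengenes,
trait association) -> ReliefF hub screening within trait-up modules and
sample clustering -> rolling-circle ORF prediction on the fixture circle ->
alternative-splicing simulation, differential PSI and RIP intersection ->
survival simulation, median dichotomization and log-rank -> gene-set
over-representation.  Every stage draws its randomness from a stage-salted
seed derived from one global seed, so stages are independently reproducible
and two runs with the same config produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from circscreen import circorf, coexnet, diffexpr, hubscreen, splicing, survstats, synthdata

log = logging.getLogger("circscreen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed salted with the CRC32 of the
    stage name, reduced below 2**31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "de": {"group_a": "IgD", "group_b": "IgG", "fc_thresh": 2.0, "p_thresh": 0.05},
    "filter": {"min_value": 1.0, "min_samples": 3},
    "wgcna": {"r2_goal": 0.85, "min_module_size": 10, "cut_rule": "gap", "default_power": 6},
    "relief": {"k_neighbors": 5, "panel_size": 25},
    "orf": {"max_traversals": 4, "min_length_aa": 20},
    "splice": {"alpha": 0.05},
    "survival": {"n_subjects": 200, "hazard_ratio": 2.0, "censor_fraction": 0.2},
    "enrich": {"universe_size": 500, "n_sets": 20, "planted": [25, 15], "n_hits": 30},
}


def _merged(config: Optional[dict]) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


@dataclass
class PipelineReport:
    seed: int
    parameters: dict
    stage_seeds: dict[str, int]
    n_probes_input: int = 0
    n_probes_filtered: int = 0
    n_de_up: int = 0
    n_de_down: int = 0
    chosen_power: int = 0
    module_count: int = 0
    trait_up_modules: list[str] = field(default_factory=list)
    candidate_probes: int = 0
    panel_size: int = 0
    panel: list[str] = field(default_factory=list)
    panel_ari: float = float("nan")
    primary_orf_length_aa: int = 0
    primary_orf_traversals: int = 0
    primary_orf_start: int = 0
    primary_orf_ires_proximal: bool = False
    significant_as_events: int = 0
    as_category_summary: dict = field(default_factory=dict)
    rip_candidates: int = 0
    top_rip_event: Optional[str] = None
    logrank_chi_square: float = float("nan")
    logrank_p: float = float("nan")
    survival_skipped: bool = False
    top_enrichment_set: Optional[str] = None
    top_enrichment_p: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def run_pipeline(config: Optional[dict] = None, outdir: Optional[str] = None) -> PipelineReport:
    cfg = _merged(config)
    seed = int(cfg["seed"])
    stages = ["simulate", "relief", "orf", "splice", "survival", "enrich"]
    seeds = {s: stage_seed(seed, s) for s in stages}
    report = PipelineReport(seed=seed, parameters=cfg, stage_seeds=seeds)

    # --- expression cohort -------------------------------------------------
    if cfg.get("simulate", True):
        log.info("[simulate] generating co-expression preset cohort")
        data = synthdata.gen_expression(synthdata.coexpression_preset(seed=seeds["simulate"]))
    else:
        from circscreen import iolib

        data = iolib.read_expression(cfg["expression_path"], cfg["annotation_path"])
    report.n_probes_input = len(data.probe_ids)

    log.info("[filter] abundance filter")
    data = diffexpr.filter_expressed(
        data, cfg["filter"]["min_value"], cfg["filter"]["min_samples"]
    )
    report.n_probes_filtered = len(data.probe_ids)

    log.info("[de] differential expression %s vs %s", cfg["de"]["group_a"], cfg["de"]["group_b"])
    de = diffexpr.differential_expression(data, cfg["de"]["group_a"], cfg["de"]["group_b"])
    de = diffexpr.classify_de(de, cfg["de"]["fc_thresh"], cfg["de"]["p_thresh"])
    report.n_de_up = sum(1 for r in de if r.call == "up")
    report.n_de_down = sum(1 for r in de if r.call == "down")

    # --- co-expression network --------------------------------------------
    log.info("[wgcna] soft threshold scan")
    scan = coexnet.soft_threshold_scan(data, r2_goal=cfg["wgcna"]["r2_goal"])
    # when no power meets the scale-free goal, fall back to the canonical
    # unsigned-network default rather than the scan's argmax (latent-factor
    # module structure is not scale-free, so the argmax is uninformative)
    power = scan.chosen_power
    if max(scan.fit_r2) < cfg["wgcna"]["r2_goal"]:
        power = cfg["wgcna"]["default_power"]
    report.chosen_power = power
    adj = coexnet.adjacency_matrix(data, power=power)
    tom = coexnet.topological_overlap(adj)
    assignment = coexnet.detect_modules(
        tom,
        min_module_size=cfg["wgcna"]["min_module_size"],
        cut_rule=cfg["wgcna"]["cut_rule"],
    )
    report.module_count = len(assignment.module_names)
    eig = coexnet.module_eigengenes(data, assignment)
    trait = {s: int(data.groups[s] == "IgD") for s in data.sample_ids}
    assoc = coexnet.module_trait_association(eig, trait)
    report.trait_up_modules = sorted(a.module for a in assoc if a.trait_up)

    # --- hub screening -----------------------------------------------------
    candidates = [
        p for p in data.probe_ids if assignment.modules.get(p) in report.trait_up_modules
    ]
    if len(candidates) < cfg["relief"]["panel_size"]:
        # fall back to all assigned probes so the panel stage stays exercisable
        candidates = [p for p in data.probe_ids if assignment.modules.get(p) != coexnet.GREY]
    report.candidate_probes = len(candidates)
    log.info("[relief] ranking %d candidate probes", len(candidates))
    ranking = hubscreen.relieff_weights(
        data.subset_probes(candidates), k=cfg["relief"]["k_neighbors"]
    )
    panel = hubscreen.select_hub_probes(ranking, k=cfg["relief"]["panel_size"])
    report.panel = panel
    report.panel_size = len(panel)
    score = hubscreen.cluster_and_score(data.subset_probes(panel))
    report.panel_ari = score.ari

    # --- circular ORF ------------------------------------------------------
    log.info("[orf] rolling-circle ORF on the fixture circle")
    circ = synthdata.circhnrnpu_preset(seed=seeds["orf"])
    calls = circorf.find_circular_orfs(
        circ, cfg["orf"]["max_traversals"], cfg["orf"]["min_length_aa"]
    )
    calls = circorf.annotate_ires(calls, circ)
    primary = circorf.primary_orf(calls)
    if primary is not None:
        report.primary_orf_length_aa = primary.length_aa
        report.primary_orf_traversals = primary.traversals
        report.primary_orf_start = primary.start
        report.primary_orf_ires_proximal = primary.ires_proximal

    # --- alternative splicing ----------------------------------------------
    log.info("[splice] differential splicing on simulated junction counts")
    as_table = synthdata.gen_as_counts(synthdata.as_preset(seed=seeds["splice"]))
    events = splicing.differential_splicing(as_table, alpha=cfg["splice"]["alpha"])
    sig = [e for e in events if e.significant]
    report.significant_as_events = len(sig)
    report.as_category_summary = {
        t: rec["label"] for t, rec in splicing.summarize_categories(sig).items()
    }
    rng = np.random.default_rng(seeds["splice"])
    rip_ids = {e.gene_id for e in sig if rng.random() < 0.5}
    rip = splicing.RipTargetSet(transcript_ids=rip_ids)
    ranked = splicing.intersect_rip_targets(events, rip)
    report.rip_candidates = len(ranked)
    report.top_rip_event = ranked[0].event_id if ranked else None

    # --- survival ----------------------------------------------------------
    if cfg.get("survival") is None:
        log.info("[survival] skipped (no survival block)")
        report.survival_skipped = True
    else:
        log.info("[survival] simulated cohort, median split, log-rank")
        surv = synthdata.gen_survival(
            synthdata.SurvSimConfig(
                n_subjects=cfg["survival"]["n_subjects"],
                hazard_ratio=cfg["survival"]["hazard_ratio"],
                censor_fraction=cfg["survival"]["censor_fraction"],
                seed=seeds["survival"],
            )
        )
        strata = survstats.dichotomize_by_expression(surv)
        groups = survstats.split_survival(surv, strata)
        res = survstats.logrank_test(groups["high"], groups["low"])
        report.logrank_chi_square = res.chi_square
        report.logrank_p = res.p

    # --- enrichment --------------------------------------------------------
    log.info("[enrich] hypergeometric over-representation")
    coll, hits = synthdata.gen_genesets(
        universe_size=cfg["enrich"]["universe_size"],
        n_sets=cfg["enrich"]["n_sets"],
        planted=tuple(cfg["enrich"]["planted"]),
        n_hits=cfg["enrich"]["n_hits"],
        seed=seeds["enrich"],
    )
    enr = survstats.ora_enrichment(hits, coll)
    if enr:
        report.top_enrichment_set = enr[0].set_name
        report.top_enrichment_p = enr[0].p

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
    return report
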