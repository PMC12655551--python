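"""End-to-end campaign orchestration.

Stages run in the fixed order simulate/ingest → enrich → consensus →
adme → hits → qsar, mirroring a consensus-docking screening campaign:
rank the library, check enrichment, keep pose-consistent compounds, apply
the drug-likeness filter, classify assayed hits, and model the confirmed
activities. Each stage is optional (present in the config or skipped),
writes its own CSV, and records a JSON-serialisable summary; all
randomness derives from one master seed through per-stage spawned seeds,
so stages are individually reproducible.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import DataError, ScreenvalError
from . import adme as adme_mod
from .consensus import consensus_filter, threshold_sweep
from .enrichment import RankedList, classify_hits, enrichment_report, roc_auc
from .io import (
    LOWER,
    read_score_table,
    write_report,
    write_screening_csv,
)
from .qsar import (
    applicability_domain,
    external_r2,
    fit_mlr,
    ga_select,
    loo_q2,
    split_train_test,
    y_randomization,
)
from .synthetic import (
    gen_ic50_table,
    gen_pose_pairs,
    gen_property_table,
    gen_qsar_table,
    gen_screening_scores,
)

STAGE_ORDER = ("simulate", "enrich", "consensus", "adme", "hits", "qsar")


def stage_seeds(master_seed: int) -> dict:
    """Independent per-stage seeds spawned from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_ORDER))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGE_ORDER, children)}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError("config must be a mapping")
    unknown = set(cfg.get("stages", {})) - set(STAGE_ORDER)
    if unknown:
        raise DataError(f"unknown stages in config: {sorted(unknown)}")
    return cfg


def _stage_enrich(cfg, records, out_dir):
    direction = cfg.get("direction", LOWER)
    fractions = cfg.get("fractions", [0.01, 0.02, 0.05, 0.10])
    ranked = RankedList.from_records(records, direction)
    rows = enrichment_report(ranked, fractions)
    write_report(rows, out_dir / "enrichment.csv")
    auc, points = roc_auc(ranked)
    write_report([{"fpr": f, "tpr": t} for f, t in points],
                 out_dir / "roc_points.csv")
    return {"auc": auc, "table": rows, "n_total": ranked.n_total,
            "hits_total": ranked.hits_total}


def _stage_consensus(cfg, seed, out_dir):
    rng = np.random.default_rng(seed)
    n_actives = cfg.get("n_actives", 30)
    n_decoys = cfg.get("n_decoys", 70)
    # actives cluster at low pose disagreement, decoys spread wide
    rmsds = np.concatenate([
        rng.uniform(cfg.get("active_rmsd_low", 0.2),
                    cfg.get("active_rmsd_high", 2.8), size=n_actives),
        rng.uniform(cfg.get("decoy_rmsd_low", 0.5),
                    cfg.get("decoy_rmsd_high", 6.0), size=n_decoys),
    ])
    labels = ["active"] * n_actives + ["decoy"] * n_decoys
    pairs = gen_pose_pairs(rmsds, seed=seed, labels=labels)
    threshold = cfg.get("threshold", 3.0)
    result = consensus_filter(pairs, threshold)
    write_report(
        [{"id": cid, "rmsd": r, "accepted": acc}
         for cid, r, acc in result.per_compound],
        out_dir / "consensus.csv")
    summary = result.summary_row()
    sweep = cfg.get("sweep")
    if sweep:
        rows = threshold_sweep(pairs, sweep)
        write_report(rows, out_dir / "consensus_sweep.csv")
        summary["sweep"] = rows
    return summary


def _stage_adme(cfg, seed, out_dir):
    n = cfg.get("n", 500)
    planted = cfg.get("planted_pass", max(1, n // 6))
    records = gen_property_table(n, planted, seed=seed)
    passed, failed = adme_mod.screen_filter(records)
    write_report(passed, out_dir / "adme_passed.csv")
    write_report(
        [{"compound_id": rec.compound_id, "reasons": ";".join(reasons)}
         for rec, reasons in failed],
        out_dir / "adme_failed.csv")
    return {"n": n, "passed": len(passed), "failed": len(failed)}


def _stage_hits(cfg, seed, out_dir):
    n = cfg.get("n", 27)
    n_active = cfg.get("n_active", 12)
    threshold = cfg.get("threshold_uM", 100.0)
    table = gen_ic50_table(n, n_active, seed=seed, threshold=threshold)
    calls, rate = classify_hits(table, threshold=threshold,
                                overrides=cfg.get("overrides", ()))
    write_report(calls, out_dir / "hit_calls.csv")
    return {"n": n, "hits": sum(c.is_hit for c in calls), "hit_rate_pct": rate}


def _stage_qsar(cfg, seed, out_dir):
    n = cfg.get("n", 15)
    noise_sd = cfg.get("noise_sd", 0.3)
    table = gen_qsar_table(n=n, noise_sd=noise_sd, seed=seed,
                           n_decoy_descriptors=cfg.get("n_decoy_descriptors", 0))
    subset_size = cfg.get("subset_size", 3)
    if table.descriptors.shape[1] > subset_size:
        names, model, _ = ga_select(
            table, subset_size=subset_size, seed=seed,
            population=cfg.get("ga_population"),
            generations=cfg.get("ga_generations"))
    else:
        names = list(table.descriptors.columns)
        model = fit_mlr(table.descriptors, table.response)
        model.q2_loo = loo_q2(table.descriptors, table.response)
    train, test = split_train_test(table.select(names),
                                   cfg.get("train_frac", 0.8), seed=seed)
    train_model = fit_mlr(train.descriptors, train.response)
    train_model.q2_loo = loo_q2(train.descriptors, train.response)
    train_model.r2_test = external_r2(train_model, test.descriptors, test.response)
    rand = y_randomization(train.descriptors, train.response,
                           n_trials=cfg.get("trials", 200), seed=seed)
    ad = applicability_domain(
        train.descriptors, train.response, train_model,
        X_query=test.descriptors, y_query=test.response,
        train_ids=train.compound_ids, query_ids=test.compound_ids,
        n_reference=table.n)
    write_report(ad, out_dir / "williams.csv")
    (out_dir / "qsar_model.json").write_text(
        json.dumps(train_model.to_dict(), indent=2), encoding="utf-8")
    return {
        "descriptors": names,
        "full_model": model.to_dict(),
        "train_model": train_model.to_dict(),
        "y_randomization": {
            "n_trials": rand.n_trials, "mean_r2": rand.mean_r2,
            "mean_q2": rand.mean_q2, "max_r2": rand.max_r2,
            "original_r2": rand.original_r2, "original_q2": rand.original_q2,
        },
        "h_star": ad[0].h_star,
        "n_out_of_domain": sum(not a.in_domain for a in ad),
    }


def run_campaign(config: dict, out_dir, master_seed: int = None) -> dict:
    """Run the configured stages in fixed order and write run_summary.json.

    A stage failure aborts the run but still writes the partial summary
    (with the failing stage named) before re-raising.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages_cfg = config.get("stages", {})
    if master_seed is None:
        master_seed = int(config.get("seed", 0))
    seeds = stage_seeds(master_seed)
    summary = {
        "config": config,
        "master_seed": master_seed,
        "stage_seeds": seeds,
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    records = None
    try:
        if "simulate" in stages_cfg:
            sim = stages_cfg["simulate"] or {}
            records = gen_screening_scores(
                sim.get("n_actives", 169), sim.get("n_decoys", 6931),
                sim.get("target_auc", 0.72), seed=seeds["simulate"])
            write_screening_csv(records, out_dir / "scores.csv")
            summary["stages"]["simulate"] = {
                "n_actives": sim.get("n_actives", 169),
                "n_decoys": sim.get("n_decoys", 6931),
                "target_auc": sim.get("target_auc", 0.72),
            }
        if "enrich" in stages_cfg:
            cfg = stages_cfg["enrich"] or {}
            if records is None:
                if "scores" not in cfg:
                    raise DataError("enrich stage needs simulated or file scores")
                records = read_score_table(cfg["scores"],
                                           cfg.get("direction", LOWER))
            summary["stages"]["enrich"] = _stage_enrich(cfg, records, out_dir)
        if "consensus" in stages_cfg:
            summary["stages"]["consensus"] = _stage_consensus(
                stages_cfg["consensus"] or {}, seeds["consensus"], out_dir)
        if "adme" in stages_cfg:
            summary["stages"]["adme"] = _stage_adme(
                stages_cfg["adme"] or {}, seeds["adme"], out_dir)
        if "hits" in stages_cfg:
            summary["stages"]["hits"] = _stage_hits(
                stages_cfg["hits"] or {}, seeds["hits"], out_dir)
        if "qsar" in stages_cfg:
            summary["stages"]["qsar"] = _stage_qsar(
                stages_cfg["qsar"] or {}, seeds["qsar"], out_dir)
    except ScreenvalError as exc:
        summary["failed_stage"] = _current_stage(summary)
        summary["error"] = str(exc)
        _write_summary(summary, out_dir)
        raise
    summary["finished"] = datetime.now(timezone.utc).isoformat()
    _write_summary(summary, out_dir)
    return summary


def _current_stage(summary: dict) -> str:
    done = set(summary["stages"])
    for name in STAGE_ORDER:
        if name not in done:
            return name
    return "unknown"


def _write_summary(summary: dict, out_dir: Path) -> None:
    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, default=str), encoding="utf-8")
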