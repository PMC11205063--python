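"""End-to-end orchestration: config, seeding, stage sequencing, reports.

``run_pipeline`` executes clean -> low-fluency exclusion -> median split ->
binarize -> frequency filter -> node equating -> cosine -> TMFG -> metrics
-> random-network baseline -> case-wise bootstrap -> comparisons (t-tests,
and the 2x2 ANOVA when two timepoints are present) and writes every
artifact, with the exact configuration and seed echoed alongside, so a rerun
with the same config is bit-identical.

One master seed deterministically derives a seed per stage (stage name
hashed), so individual stages can be rerun without disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import fluency_data as fd
from .construction import cosine_similarity, equate_nodes, export_network, tmfg
from .errors import FluencyNetError
from .inference import (anova_2x2, casewise_bootstrap, compare_independent,
                        compare_paired, descriptive_stats,
                        random_network_test, BOOTSTRAP_METRICS)
from .metrics import metric_set

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """Fully serializable run configuration; echoed into the output dir."""

    fluency_path: str = ""
    scores_path: str = ""
    normalization_path: str | None = None
    exclusion_path: str | None = None
    out_dir: str = "results/pipeline"
    tasks: tuple[str, ...] = ("domain_specific", "domain_general")
    min_responses: int = 3
    min_producers: int = 2
    B: int = 1000
    M: int = 1000
    cc_variant: str = "local_average"
    louvain_runs: int = 10
    bootstrap_louvain_runs: int = 3
    master_seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        cfg.tasks = tuple(cfg.tasks)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _cell_name(task: str, group: str, tp: str) -> str:
    return f"{task}__{group}__{tp}"


def run_pipeline(cfg: PipelineConfig,
                 fluency: pd.DataFrame | None = None,
                 scores: pd.DataFrame | None = None) -> dict:
    """Run the full analysis; returns the report dict and writes artifacts.

    ``fluency`` and ``scores`` may be passed in-memory (e.g. straight from
    the simulator); otherwise they are read from the configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())
    provenance = {"config_hash": cfg.digest(), "master_seed": cfg.master_seed}

    # ---- data stage ------------------------------------------------------
    if fluency is None:
        fluency = fd.load_fluency(cfg.fluency_path)
    else:
        fluency = fd.validate_fluency_table(fluency)
    if scores is None:
        scores = fd.load_scores(cfg.scores_path)
    rules = fd.load_cleaning_rules(cfg.normalization_path, cfg.exclusion_path)
    ds = fd.clean_responses(fluency, rules, scores=scores)
    ds = fd.exclude_low_fluency(ds, min_responses=cfg.min_responses)
    ds.responses.to_csv(out / "cleaned_responses.csv", index=False)
    ds.cleaning_log.to_csv(out / "cleaning_log.csv", index=False)

    score_map = (ds.scores.set_index("participant_id")["score"]
                 .loc[lambda s: s.index.isin(ds.participants)])
    assignment = fd.median_split(score_map)
    frame = assignment.to_frame()
    frame["median"] = assignment.median
    frame.to_csv(out / "group_assignment.csv", index=False)

    analyzed = {"low": assignment.low, "high": assignment.high}
    timepoints = ds.timepoints
    tasks = [t for t in cfg.tasks if t in ds.tasks]
    if not tasks:
        raise FluencyNetError("none of the configured tasks are in the data")

    report: dict = {"provenance": provenance,
                    "groups": assignment.counts(),
                    "median": assignment.median,
                    "tasks": {}}

    metric_rows, randnet_rows, comparison_rows, anova_rows = [], [], [], []

    for task in tasks:
        # ---- binarize, frequency-filter on the analyzed sample, equate ---
        cells: dict[tuple[str, str], pd.DataFrame] = {}
        for tp in timepoints:
            overall = fd.build_response_matrix(
                ds, task, tp, scope=assignment.low + assignment.high)
            overall = fd.frequency_filter(overall,
                                          min_producers=cfg.min_producers)
            for group, members in analyzed.items():
                cells[(group, tp)] = overall.loc[
                    overall.index.isin(members)]
        equated = equate_nodes({f"{g}:{tp}": m
                                for (g, tp), m in cells.items()})
        cells = {k: equated[f"{k[0]}:{k[1]}"] for k in cells}
        node_universe = list(next(iter(cells.values())).columns)

        # ---- networks and observed metrics -------------------------------
        nets, dists = {}, {}
        for (group, tp), mat in sorted(cells.items()):
            name = _cell_name(task, group, tp)
            sim = cosine_similarity(mat.loc[:, mat.sum(axis=0) > 0])
            g = tmfg(sim, provenance={"task": task, "group": group,
                                      "timepoint": tp, **provenance})
            nets[(group, tp)] = g
            export_network(g, out / f"network_{name}.edgelist.tsv",
                           "edge_list")
            export_network(g, out / f"network_{name}.graphml", "graphml")
            ms = metric_set(g, seed=stage_seed(cfg.master_seed,
                                               f"metrics:{name}"),
                            cc_variant=cfg.cc_variant,
                            louvain_runs=cfg.louvain_runs)
            metric_rows.append({"task": task, "group": group,
                                "timepoint": tp, **ms.to_dict()})

            if cfg.M:
                rn = random_network_test(
                    g, M=cfg.M,
                    seed=stage_seed(cfg.master_seed, f"randnet:{name}"))
                for rep in rn.values():
                    randnet_rows.append({"task": task, "group": group,
                                         "timepoint": tp, **asdict(rep)})

            dists[(group, tp)] = casewise_bootstrap(
                mat, node_universe=node_universe, B=cfg.B,
                seed=stage_seed(cfg.master_seed, f"bootstrap:{name}"),
                label=name, louvain_runs=cfg.bootstrap_louvain_runs)
            dists[(group, tp)].values.to_csv(
                out / f"bootstrap_{name}.csv", index=False)

        # ---- comparisons --------------------------------------------------
        for metric in BOOTSTRAP_METRICS:
            # groups within each timepoint (high vs low, independent)
            for tp in timepoints:
                res = compare_independent(dists[("high", tp)],
                                          dists[("low", tp)], metric)
                comparison_rows.append({"task": task, "contrast":
                                        f"high_vs_low@{tp}",
                                        **res.to_dict()})
            # timepoints within each group (paired by iteration index)
            for group in analyzed:
                for tp_a, tp_b in combinations(timepoints, 2):
                    res = compare_paired(dists[(group, tp_a)],
                                         dists[(group, tp_b)], metric)
                    comparison_rows.append({"task": task, "contrast":
                                            f"{group}:{tp_a}_vs_{tp_b}",
                                            **res.to_dict()})
            if len(timepoints) == 2:
                res = anova_2x2({k: dists[k] for k in dists}, metric)
                for eff in res.effects:
                    anova_rows.append({"task": task, "metric": metric,
                                       **asdict(eff)})

        report["tasks"][task] = {
            "n_nodes": len(node_universe),
            "cells": {_cell_name(task, g_, tp): nets[(g_, tp)].number_of_edges()
                      for (g_, tp) in nets},
        }

    # ---- descriptive correlations ---------------------------------------
    analyzed_ids = assignment.low + assignment.high
    sc = ds.scores.set_index("participant_id").loc[
        lambda df: df.index.isin(analyzed_ids)]
    fl = ds.fluency_scores()
    fluency_vars = {}
    for task in tasks:
        for tp in timepoints:
            sub = fl.xs((task, tp), level=("task", "timepoint"))
            fluency_vars[f"fluency_{task}_{tp}"] = sub.loc[
                sub.index.isin(analyzed_ids)]
    grades = sc["grade"] if sc["grade"].notna().any() else None
    corr = descriptive_stats(sc["score"], grades, fluency_vars)
    corr.to_csv(out / "correlations.csv", index=False)

    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    if randnet_rows:
        pd.DataFrame(randnet_rows).to_csv(out / "random_network_tests.csv",
                                          index=False)
    pd.DataFrame(comparison_rows).to_csv(out / "comparisons.csv", index=False)
    if anova_rows:
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

    report["metrics"] = metric_rows
    report["comparisons"] = comparison_rows
    report["anova"] = anova_rows
    report["random_network_tests"] = randnet_rows
    report["correlations"] = corr.to_dict(orient="records")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    logger.info("pipeline complete: artifacts in %s", out)
    return report
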