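"""Synthetic verbal-fluency data with known ground-truth network structure.

Each group x timepoint cell is assigned a planted semantic network (a
connected Watts-Strogatz small-world graph or a planted-partition graph)
whose global metrics are recorded as ground truth.  Simulated participants
produce fluency lists by a censored random walk over that network — the
standard generative account of fluency production: a walk over semantic
memory reporting only first visits, with an occasional uniform restart
standing in for strategic jumps between retrieval patches.  List lengths are
truncated-normal integers parameterized to typical fluency magnitudes
(domain-specific lists around 10-13 responses, domain-general around 16-20),
never below 3 so simulated participants clear the low-fluency exclusion by
construction.

The emitted tables use exactly the dialects the loading module reads, with
tokens already canonical, so a simulated dataset passes validation with zero
cleaning actions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FluencyNetError
from .metrics import MetricSet, metric_set

logger = logging.getLogger(__name__)

TASKS = ("domain_specific", "domain_general")


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Recipe for one cell's latent semantic network.

    ``family`` is ``small_world`` (params: ``n_words``, ``k_neighbors``,
    ``rewire_prob``) or ``planted_partition`` (params: ``n_words``,
    ``n_blocks``, ``p_in``, ``p_out``).
    """

    family: str
    params: Mapping[str, float]
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.params
        if self.family == "small_world":
            if int(p["k_neighbors"]) % 2 != 0:
                raise ValueError("k_neighbors must be even for a ring lattice")
        elif self.family == "planted_partition":
            if not p["p_in"] > p["p_out"]:
                raise ValueError("planted partition needs p_in > p_out")
        else:
            raise ValueError(f"unknown network family: {self.family!r}")


def make_planted_network(spec: PlantedNetworkSpec,
                         token_prefix: str = "w") -> tuple[nx.Graph, MetricSet]:
    """Generate a connected planted network plus its ground-truth metrics.

    Regenerates with incremented seeds up to 100 times if the draw is
    disconnected; node labels are canonical tokens ``w000, w001, ...``.
    """
    p = spec.params
    n = int(p["n_words"])
    g = None
    for attempt in range(100):
        s = spec.seed + attempt
        if spec.family == "small_world":
            cand = nx.watts_strogatz_graph(n, int(p["k_neighbors"]),
                                           float(p["rewire_prob"]), seed=s)
        else:
            blocks = int(p["n_blocks"])
            if n % blocks:
                raise ValueError("n_words must divide evenly into n_blocks")
            cand = nx.planted_partition_graph(blocks, n // blocks,
                                              float(p["p_in"]),
                                              float(p["p_out"]), seed=s)
        if nx.is_connected(cand):
            g = cand
            break
    if g is None:
        raise FluencyNetError(
            f"could not generate a connected {spec.family} network "
            f"in 100 attempts ({spec.label})")
    width = max(3, len(str(n - 1)))
    mapping = {i: f"{token_prefix}{i:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    g.graph["label"] = spec.label
    truth = metric_set(g, seed=spec.seed)
    return g, truth


def simulate_participant(g: nx.Graph, length: int, restart_prob: float,
                         rng: np.random.Generator) -> list[str]:
    """One fluency list: a censored random walk reporting first visits.

    Starts at a uniform node; at each step, with probability
    ``restart_prob`` jumps to a uniform node, otherwise moves to a uniform
    neighbor; a node is appended to the list on its first visit only.  The
    walk stops when ``length`` unique tokens have been emitted or after
    ``1000 * length`` steps.
    """
    if length < 3:
        raise ValueError("list length must be >= 3")
    nodes = sorted(g.nodes)
    neighbors = {u: sorted(g.neighbors(u)) for u in nodes}
    current = nodes[rng.integers(len(nodes))]
    visited = [current]
    seen = {current}
    cap = 1000 * length
    for _ in range(cap):
        if len(visited) >= length:
            break
        if rng.random() < restart_prob:
            current = nodes[rng.integers(len(nodes))]
        else:
            nbrs = neighbors[current]
            current = nbrs[rng.integers(len(nbrs))]
        if current not in seen:
            seen.add(current)
            visited.append(current)
    return visited


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation design.

    One planted network per task x (group, timepoint) cell; per-group list
    lengths per task as (mean, sd) of a truncated normal (floor 3);
    knowledge scores as per-group integer normals chosen well-separated so a
    median split recovers the planted groups.
    """

    participants_per_group: int = 60
    groups: tuple[str, ...] = ("low", "high")
    timepoints: tuple[str, ...] = ("T1",)
    specs: Mapping[str, Mapping[tuple[str, str], PlantedNetworkSpec]] = \
        field(default_factory=dict)
    list_length: Mapping[str, Mapping[str, tuple[float, float]]] = \
        field(default_factory=lambda: {
            "domain_specific": {"low": (9.7, 4.1), "high": (10.2, 3.9)},
            "domain_general": {"low": (16.4, 5.6), "high": (17.4, 4.6)},
        })
    restart_prob: float = 0.05
    score_model: Mapping[str, tuple[float, float]] = \
        field(default_factory=lambda: {"low": (14.0, 3.0), "high": (26.0, 3.0)})
    master_seed: int = 0


def default_config(master_seed: int = 0,
                   participants_per_group: int = 60,
                   timepoints: tuple[str, ...] = ("T1",),
                   n_words: int = 60,
                   rewire: Mapping[str, float] | None = None) -> SimulationConfig:
    """A ready-to-run design: small-world planted networks per cell, with
    the low group's network more rewired (less clustered) than the high
    group's by default."""
    rewire = rewire or {"low": 0.3, "high": 0.05}
    specs: dict[str, dict[tuple[str, str], PlantedNetworkSpec]] = {}
    for t_i, task in enumerate(TASKS):
        specs[task] = {}
        for g_i, group in enumerate(("low", "high")):
            for tp_i, tp in enumerate(timepoints):
                specs[task][(group, tp)] = PlantedNetworkSpec(
                    family="small_world",
                    params={"n_words": n_words, "k_neighbors": 6,
                            "rewire_prob": rewire[group]},
                    label=f"{task}:{group}:{tp}",
                    seed=master_seed + 1000 * t_i + 100 * g_i + 10 * tp_i + 1,
                )
    return SimulationConfig(participants_per_group=participants_per_group,
                            timepoints=timepoints, specs=specs,
                            master_seed=master_seed)


def _draw_length(mean: float, sd: float, n_words: int,
                 rng: np.random.Generator) -> int:
    length = int(round(rng.normal(mean, sd)))
    return max(3, min(length, n_words))


def simulate_study(cfg: SimulationConfig) -> dict:
    """Simulate a full study and emit pipeline-ready tables.

    Returns a dict with ``fluency`` (long-format response table),
    ``scores`` (participant_id, score, grade), ``group_truth``
    (participant_id, group) and ``network_truth`` (per task x cell planted
    :class:`~fluencynet.metrics.MetricSet` rows, plus the planted graphs
    under ``networks``).  Fully deterministic given ``cfg.master_seed``.
    """
    rng = np.random.default_rng(cfg.master_seed)
    nets: dict[tuple[str, str, str], nx.Graph] = {}
    truth_rows = []
    for task in cfg.specs:
        for (group, tp), spec in cfg.specs[task].items():
            prefix = "ds_" if task == "domain_specific" else "dg_"
            g, truth = make_planted_network(spec, token_prefix=prefix)
            nets[(task, group, tp)] = g
            truth_rows.append({"task": task, "group": group, "timepoint": tp,
                               **truth.to_dict()})

    participants = []
    for g_i, group in enumerate(cfg.groups):
        for k in range(cfg.participants_per_group):
            participants.append((f"p{g_i}{k:03d}", group))

    fluency_rows = []
    score_rows = []
    for pid, group in participants:
        mu, sd = cfg.score_model[group]
        score = int(round(rng.normal(mu, sd)))
        # grade loosely tracks the knowledge score (1-9 ordinal, noisy)
        grade = int(np.clip(round(score / 4.0 + rng.normal(0, 1.2)), 1, 9))
        score_rows.append({"participant_id": pid, "score": score,
                           "grade": grade})
        for task in cfg.specs:
            mean, sdev = cfg.list_length[task][group]
            for tp in cfg.timepoints:
                g = nets[(task, group, tp)]
                length = _draw_length(mean, sdev, g.number_of_nodes(), rng)
                for _ in range(100):
                    tokens = simulate_participant(g, length,
                                                  cfg.restart_prob, rng)
                    if len(tokens) >= 3:
                        break
                else:  # pragma: no cover - walk exhaustion is pathological
                    raise FluencyNetError(f"walk for {pid} kept stalling")
                for pos, tok in enumerate(tokens, start=1):
                    fluency_rows.append({
                        "participant_id": pid, "task": task, "timepoint": tp,
                        "position": pos, "token": tok})

    fluency = pd.DataFrame(fluency_rows,
                           columns=["participant_id", "task", "timepoint",
                                    "position", "token"])
    scores = pd.DataFrame(score_rows)
    group_truth = pd.DataFrame(
        [{"participant_id": pid, "group": grp} for pid, grp in participants])
    network_truth = pd.DataFrame(truth_rows)
    logger.info("simulated %d participants, %d responses",
                len(participants), len(fluency))
    return {"fluency": fluency, "scores": scores, "group_truth": group_truth,
            "network_truth": network_truth, "networks": nets}
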