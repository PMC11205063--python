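import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

logging.getLogger("fluencynet").setLevel(logging.ERROR)


@pytest.fixture
def toy_fluency() -> pd.DataFrame:
    """One participant, three animal responses, positions 1..3."""
    return pd.DataFrame({
        "participant_id": ["p1"] * 3,
        "task": ["domain_general"] * 3,
        "timepoint": ["T1"] * 3,
        "position": [1, 2, 3],
        "token": ["dog", "cat", "emu"],
    })


@pytest.fixture
def two_participant_dataset() -> pd.DataFrame:
    """Two participants with lists [a, b] and [b, c]."""
    rows = []
    for pid, tokens in [("p1", ["a", "b"]), ("p2", ["b", "c"])]:
        for pos, tok in enumerate(tokens, 1):
            rows.append({"participant_id": pid, "task": "domain_general",
                         "timepoint": "T1", "position": pos, "token": tok})
    return pd.DataFrame(rows)


def random_positive_similarity(n: int, seed: int) -> pd.DataFrame:
    """Strictly positive symmetric similarity matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.01, 1.0, size=(n, n))
    s = (a + a.T) / 2.0
    np.fill_diagonal(s, 1.0)
    labels = [f"w{i:03d}" for i in range(n)]
    return pd.DataFrame(s, index=labels, columns=labels)


def random_small_graph(rng: np.random.Generator, n_max: int = 8,
                       require_edge: bool = True) -> nx.Graph:
    """A random simple graph with 3..n_max nodes (used by oracle batteries)."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not require_edge or g.number_of_edges() >= 1:
            return g
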