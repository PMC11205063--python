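"""Inferential machinery for comparing group-based networks.

Group-based network estimation yields a single CC/ASPL/Q value per group, so
group differences are tested on sampling distributions built by a case-wise
bootstrap: participants are resampled with replacement, the network is
re-estimated (cosine + TMFG) from each resample, and the metric distributions
are compared with classical pooled-variance t-tests (independent between
groups, paired by iteration index across timepoints), a 2x2 fixed-effects
ANOVA on the replicate values, and BIC-approximated Bayes factors.  Observed
networks are additionally benchmarked against uniform random graphs matched
on node and edge counts.

Degrees of freedom scale with the number of bootstrap iterations B
(independent: 2B-2, paired: B-1, ANOVA denominator: 4B-4), so p-values are
resolution-dependent; effect sizes are the primary output, and every
comparison logs that caveat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .construction import cosine_similarity, tmfg
from .errors import EmptyResultError, IntegrityError, UndefinedStatisticError
from .metrics import MetricSet, metric_set

logger = logging.getLogger(__name__)

BOOTSTRAP_METRICS = ("cc", "aspl", "q")


# ---------------------------------------------------------------------------
# random-network baseline


@dataclass(frozen=True)
class RandomNetReport:
    """Observed metric vs the distribution over M matched random graphs."""

    metric: str
    observed: float
    m_graphs: int
    null_mean: float
    null_sd: float
    p_value: float


def random_network_test(g: nx.Graph, M: int = 1000, seed: int = 0,
                        metrics: Sequence[str] = BOOTSTRAP_METRICS,
                        louvain_runs: int = 3) -> dict[str, RandomNetReport]:
    """Compare a network's metrics against uniform G(n, m) random graphs.

    Draws ``M`` simple random graphs with the observed node and edge counts,
    computes each requested metric on them, and reports the empirical
    two-sided p-value ``(1 + #{null at least as extreme}) / (M + 1)`` where
    extremeness is distance from the null mean.  The smallest attainable p
    is therefore ``1 / (M + 1)``.
    """
    from . import metrics as _metrics_mod

    if M < 19:
        raise ValueError("M must be >= 19 for a meaningful p-value")
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m > n * (n - 1) // 2 or (m < 1 and ("aspl" in metrics or "q" in metrics)):
        raise IntegrityError(f"edge count {m} infeasible for {n} nodes")

    def evaluate(graph: nx.Graph, s: int) -> dict[str, float]:
        vals = {}
        for k in metrics:
            if k == "cc":
                vals[k] = _metrics_mod.clustering_coefficient(graph)
            elif k == "aspl":
                vals[k] = _metrics_mod.aspl(graph)
            elif k == "q":
                vals[k] = _metrics_mod.modularity_q(
                    graph, seed=s, runs=louvain_runs)[0]
            elif k == "efficiency":
                vals[k] = _metrics_mod.global_efficiency(graph)
            else:
                raise ValueError(f"unknown metric: {k!r}")
        return vals

    rng = np.random.default_rng(seed)
    obs = evaluate(g, seed)
    null = {k: np.empty(M) for k in metrics}
    for i in range(M):
        gi = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        mi = evaluate(gi, int(rng.integers(2**31)))
        for k in metrics:
            null[k][i] = mi[k]
    out = {}
    for k in metrics:
        mu, sd = float(null[k].mean()), float(null[k].std(ddof=1))
        dist = abs(obs[k] - mu)
        p = (1.0 + int(np.sum(np.abs(null[k] - mu) >= dist))) / (M + 1.0)
        out[k] = RandomNetReport(metric=k, observed=float(obs[k]),
                                 m_graphs=M, null_mean=mu, null_sd=sd,
                                 p_value=p)
    return out


# ---------------------------------------------------------------------------
# case-wise bootstrap


@dataclass
class BootstrapDistribution:
    """B replicate metric sets for one (group, timepoint, task) cell.

    ``values`` has one row per iteration and one column per metric;
    regeneration with the same seed is bit-identical.
    """

    label: str
    B: int
    seed: int
    values: pd.DataFrame
    n_redraws: int = 0

    def metric(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()


def casewise_bootstrap(matrix: pd.DataFrame,
                       node_universe: Iterable[str] | None = None,
                       B: int = 1000, seed: int = 0, label: str = "",
                       metrics: Sequence[str] = BOOTSTRAP_METRICS,
                       louvain_runs: int = 3) -> BootstrapDistribution:
    """Bootstrap sampling distribution of network metrics for one cell.

    Each iteration resamples participants (rows) with replacement at the
    original n, restricts columns to the equated ``node_universe`` (fixed
    from the full sample, not recomputed per replicate), drops response
    types nobody in the resample produced, and recomputes
    cosine -> TMFG -> metrics.  A replicate with fewer than 4 produced
    response types is redrawn (logged); 100 consecutive failures abort.
    """
    if matrix.shape[0] < 4:
        raise EmptyResultError("case-wise bootstrap needs >= 4 participants")
    if node_universe is not None:
        cols = [c for c in matrix.columns if c in set(node_universe)]
        matrix = matrix.loc[:, cols]
    X = matrix.to_numpy(dtype=np.int8)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    n_redraws = 0
    b = 0
    consecutive_failures = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        rep_seed = int(rng.integers(2**31))
        sub = X[idx]
        produced = sub.sum(axis=0) > 0
        if int(produced.sum()) < 4:
            n_redraws += 1
            consecutive_failures += 1
            logger.info("bootstrap replicate redrawn (<4 produced nodes)")
            if consecutive_failures >= 100:
                raise EmptyResultError(
                    "100 consecutive bootstrap replicates had < 4 nodes")
            continue
        consecutive_failures = 0
        cols = matrix.columns[produced]
        rep = pd.DataFrame(sub[:, produced], columns=cols)
        sim = cosine_similarity(rep)
        g = tmfg(sim)
        ms = metric_set(g, seed=rep_seed, louvain_runs=louvain_runs)
        rows.append({k: getattr(ms, k) for k in metrics})
        b += 1
    values = pd.DataFrame(rows, columns=list(metrics))
    return BootstrapDistribution(label=label, B=B, seed=seed, values=values,
                                 n_redraws=n_redraws)


# ---------------------------------------------------------------------------
# comparisons


@dataclass(frozen=True)
class ComparisonResult:
    """A two-condition comparison of one bootstrap metric distribution."""

    metric: str
    design: str  # "independent" | "paired"
    t: float
    df: int
    p: float
    d: float
    ci95: tuple[float, float]
    bf10: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95_low"], d["ci95_high"] = d.pop("ci95")
        return d


def _gaussian_bic(rss: float, n: int, k_means: int) -> float:
    """BIC of a fixed-variance-profile Gaussian mean model.

    ``n ln(RSS/n) + k ln(n)`` with ``k`` counting mean parameters; the
    shared variance parameter contributes equally to both models in a
    comparison and cancels in the BIC difference.
    """
    if rss <= 0:
        raise UndefinedStatisticError("zero residual sum of squares")
    return n * math.log(rss / n) + k_means * math.log(n)


def bf10_bic(bic_null: float, bic_alt: float) -> float:
    """Bayes factor for the alternative from two BICs:
    ``BF10 = exp((BIC_null - BIC_alt) / 2)``.  BF10 >= 3 is conventionally
    read as evidence comparable to p < .05."""
    if not (math.isfinite(bic_null) and math.isfinite(bic_alt)):
        raise ValueError("BIC values must be finite")
    return math.exp((bic_null - bic_alt) / 2.0)


def compare_independent(a: BootstrapDistribution | np.ndarray,
                        b: BootstrapDistribution | np.ndarray,
                        metric: str = "cc") -> ComparisonResult:
    """Pooled-variance (Student) independent-samples t-test on one metric.

    df = 2B - 2.  Cohen's d uses the pooled standard deviation; the 95% CI
    is on the mean difference; BF10 comes from the BIC difference between
    the common-mean and two-means Gaussian models on the replicate values.
    """
    x = a.metric(metric) if isinstance(a, BootstrapDistribution) else np.asarray(a, float)
    y = b.metric(metric) if isinstance(b, BootstrapDistribution) else np.asarray(b, float)
    na, nb = len(x), len(y)
    df = na + nb - 2
    sp2 = (((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df)
    if sp2 == 0:
        raise UndefinedStatisticError("zero pooled variance: t undefined")
    diff = x.mean() - y.mean()
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = diff / se
    p = 2.0 * st.t.sf(abs(t), df)
    d = diff / math.sqrt(sp2)
    tcrit = st.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    pooled = np.concatenate([x, y])
    rss0 = float(np.sum((pooled - pooled.mean()) ** 2))
    rss1 = float(np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2))
    bf = bf10_bic(_gaussian_bic(rss0, na + nb, 1),
                  _gaussian_bic(rss1, na + nb, 2))
    logger.info("bootstrap comparison dfs scale with B; interpret p with d")
    return ComparisonResult(metric=metric, design="independent", t=float(t),
                            df=int(df), p=float(p), d=float(d),
                            ci95=(float(ci[0]), float(ci[1])), bf10=bf,
                            mean_a=float(x.mean()), mean_b=float(y.mean()),
                            sd_a=float(x.std(ddof=1)), sd_b=float(y.std(ddof=1)))


def compare_paired(a: BootstrapDistribution | np.ndarray,
                   b: BootstrapDistribution | np.ndarray,
                   metric: str = "cc") -> ComparisonResult:
    """Paired t-test on per-iteration differences (pairing by bootstrap
    iteration index); df = B - 1.  Cohen's d is the standardized mean
    difference of the paired deltas; BF10 compares the zero-mean vs
    free-mean Gaussian models on the differences."""
    x = a.metric(metric) if isinstance(a, BootstrapDistribution) else np.asarray(a, float)
    y = b.metric(metric) if isinstance(b, BootstrapDistribution) else np.asarray(b, float)
    if len(x) != len(y):
        raise ValueError("paired comparison needs equal iteration counts")
    delta = x - y
    n = len(delta)
    df = n - 1
    sd = delta.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero difference variance: t undefined")
    se = sd / math.sqrt(n)
    t = delta.mean() / se
    p = 2.0 * st.t.sf(abs(t), df)
    d = delta.mean() / sd
    tcrit = st.t.ppf(0.975, df)
    ci = (delta.mean() - tcrit * se, delta.mean() + tcrit * se)
    rss0 = float(np.sum(delta ** 2))
    rss1 = float(np.sum((delta - delta.mean()) ** 2))
    bf = bf10_bic(_gaussian_bic(rss0, n, 0), _gaussian_bic(rss1, n, 1))
    logger.info("bootstrap comparison dfs scale with B; interpret p with d")
    return ComparisonResult(metric=metric, design="paired", t=float(t),
                            df=int(df), p=float(p), d=float(d),
                            ci95=(float(ci[0]), float(ci[1])), bf10=bf,
                            mean_a=float(x.mean()), mean_b=float(y.mean()),
                            sd_a=float(x.std(ddof=1)), sd_b=float(y.std(ddof=1)))


# ---------------------------------------------------------------------------
# 2x2 ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_squared: float


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects knowledge x timepoint ANOVA on bootstrap replicates."""

    metric: str
    effects: tuple[AnovaEffect, ...]

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.effects])


def anova_2x2(cells: Mapping[tuple[str, str], BootstrapDistribution | np.ndarray],
              metric: str = "cc") -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on the 4B replicate
    values of one metric.

    ``cells`` maps (knowledge, timepoint) to a bootstrap distribution; all
    four cells must have equal B.  Each effect has 1 numerator df; the
    denominator df is 4B - 4.  Effect sizes are eta squared
    (SS_effect / SS_total).
    """
    if len(cells) != 4:
        raise ValueError("2x2 ANOVA needs exactly four cells")
    frames = []
    sizes = set()
    for (know, tp), dist in cells.items():
        v = dist.metric(metric) if isinstance(dist, BootstrapDistribution) \
            else np.asarray(dist, float)
        sizes.add(len(v))
        frames.append(pd.DataFrame({"value": v, "knowledge": know,
                                    "timepoint": tp}))
    if len(sizes) != 1:
        raise ValueError("all cells must have the same B")
    data = pd.concat(frames, ignore_index=True)
    if np.ptp(data["value"].to_numpy()) == 0:
        raise UndefinedStatisticError("zero total variance: ANOVA undefined")
    model = smf.ols("value ~ C(knowledge) * C(timepoint)", data=data).fit()
    tab = anova_lm(model, typ=2)
    ss_total = float(tab["sum_sq"].sum())
    df_den = int(tab.loc["Residual", "df"])
    names = {"C(knowledge)": "knowledge", "C(timepoint)": "timepoint",
             "C(knowledge):C(timepoint)": "interaction"}
    effects = []
    for key, name in names.items():
        row = tab.loc[key]
        effects.append(AnovaEffect(
            effect=name, F=float(row["F"]), df_num=int(row["df"]),
            df_den=df_den, p=float(row["PR(>F)"]),
            eta_squared=float(row["sum_sq"] / ss_total)))
    return AnovaResult(metric=metric, effects=tuple(effects))


# ---------------------------------------------------------------------------
# descriptive correlations


def descriptive_stats(scores: pd.Series, grades: pd.Series | None = None,
                      fluency: Mapping[str, pd.Series] | None = None,
                      log_grades: bool = True) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among knowledge-test scores,
    (log-transformed) self-reported grades, and fluency scores.

    Grades are natural-log transformed before analysis (they are typically
    strongly positively skewed); missing grades are excluded pairwise.  A
    constant variable yields a missing (NaN) correlation, reported rather
    than raised.
    """
    variables: dict[str, pd.Series] = {"score": scores.astype(float)}
    if grades is not None:
        g = grades.astype(float)
        if log_grades:
            if (g.dropna() <= 0).any():
                raise ValueError("grades must be positive for log transform")
            g = np.log(g)
        variables["grade"] = g
    for name, series in (fluency or {}).items():
        variables[name] = series.astype(float)

    names = list(variables)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = variables[names[i]], variables[names[j]]
            pair = pd.concat([x, y], axis=1, join="inner").dropna()
            n = len(pair)
            if n < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                r, p = float("nan"), float("nan")
            else:
                r, p = st.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"var1": names[i], "var2": names[j], "n": n,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["var1", "var2", "n", "r", "p"])
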