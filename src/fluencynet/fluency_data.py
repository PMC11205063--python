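"""Loading, cleaning and binarizing verbal-fluency responses.

A fluency dataset is a long table of ordered free responses — one row per
(participant, task, timepoint, position, token).  Cleaning normalizes tokens
through a user-supplied dictionary (a deterministic stand-in for manual
expert spell-checking), drops non-category intrusions via an exclusion list,
and removes within-participant repetitions.  Participants producing fewer
than ``min_responses`` tokens on any list are excluded from all tasks, and
knowledge groups are formed by a median split on test scores with
median-valued participants assigned to neither group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyResultError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("participant_id", "task", "timepoint", "position", "token")

_LIST_KEY = ["participant_id", "task", "timepoint"]


# ---------------------------------------------------------------------------
# loading


def load_fluency(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format fluency table from delimited text.

    Parameters
    ----------
    path
        UTF-8 comma- or tab-delimited file with columns ``participant_id``,
        ``task``, ``timepoint``, ``position``, ``token``.
    sep
        Field delimiter; ``None`` sniffs comma vs tab.

    Returns
    -------
    pandas.DataFrame
        Validated table.  Positions within each (participant, task,
        timepoint) list are re-indexed to a contiguous ``1..k`` sequence
        (order preserved) with a warning when gaps were present.

    Raises
    ------
    SchemaError
        A required column is missing.
    IntegrityError
        Duplicate (participant, task, timepoint, position) keys.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"fluency file not found: {path}")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype={"participant_id": str, "token": str})
    return validate_fluency_table(df)


def validate_fluency_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an in-memory long-format fluency table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["token"] = df["token"].astype(str)
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
    if (df["position"] < 1).any():
        raise IntegrityError("positions must be positive integers")

    key = _LIST_KEY + ["position"]
    dup = df.duplicated(subset=key)
    if dup.any():
        bad = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(
            f"duplicate (participant, task, timepoint, position) key: {bad}")

    df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    reindexed = df.groupby(_LIST_KEY, sort=False)["position"].cumcount() + 1
    if (reindexed != df["position"]).any():
        n_fixed = int((reindexed != df["position"]).sum())
        logger.warning("re-indexed %d non-contiguous positions to 1..k", n_fixed)
        df["position"] = reindexed

    for (task, tp), sub in df.groupby(["task", "timepoint"], sort=True):
        logger.info("loaded %d responses for task=%s timepoint=%s",
                    len(sub), task, tp)
    return df


def load_scores(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the per-participant scores table (``participant_id``, ``score``,
    optional ``grade`` — a 1-9 ordinal of self-reported course grade)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype={"participant_id": str})
    missing = [c for c in ("participant_id", "score") if c not in df.columns]
    if missing:
        raise SchemaError(f"scores file missing column(s): {', '.join(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if "grade" not in df.columns:
        df["grade"] = np.nan
    return df.loc[:, ["participant_id", "score", "grade"]]


# ---------------------------------------------------------------------------
# cleaning rules


@dataclass(frozen=True)
class CleaningRules:
    """Deterministic token-cleaning policy.

    ``normalization_map`` maps response variants (misspellings, compounds,
    root-word variants) to canonical tokens and must be idempotent: mapping a
    canonical token returns itself.  ``exclusion_list`` holds non-category
    intrusions (e.g. "dragon" in an animal task) dropped after normalization.
    """

    normalization_map: Mapping[str, str] = field(default_factory=dict)
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    case_fold: bool = True
    strip_whitespace: bool = True

    def __post_init__(self) -> None:
        for variant, canon in self.normalization_map.items():
            if self.normalization_map.get(canon, canon) != canon:
                raise IntegrityError(
                    f"normalization map is not idempotent: "
                    f"{variant!r} -> {canon!r} -> "
                    f"{self.normalization_map[canon]!r}")

    def apply(self, token: str) -> str | None:
        """Return the canonical token, or ``None`` if excluded."""
        t = token
        if self.strip_whitespace:
            t = t.strip()
        if self.case_fold:
            t = t.casefold()
        t = self.normalization_map.get(t, t)
        if t in self.exclusion_list or not t:
            return None
        return t


def load_cleaning_rules(normalization_path: str | Path | None = None,
                        exclusion_path: str | Path | None = None,
                        case_fold: bool = True,
                        strip_whitespace: bool = True) -> CleaningRules:
    """Build :class:`CleaningRules` from a two-column (variant, canonical)
    delimited file and a one-token-per-line exclusion file."""
    nmap: dict[str, str] = {}
    if normalization_path is not None:
        tab = pd.read_csv(normalization_path, sep=None, engine="python",
                          header=None, names=["variant", "canonical"],
                          dtype=str, comment="#")
        for _, row in tab.iterrows():
            nmap[str(row["variant"]).strip()] = str(row["canonical"]).strip()
    excl: set[str] = set()
    if exclusion_path is not None:
        for line in Path(exclusion_path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                excl.add(line)
    return CleaningRules(normalization_map=nmap, exclusion_list=frozenset(excl),
                         case_fold=case_fold, strip_whitespace=strip_whitespace)


# ---------------------------------------------------------------------------
# cleaned dataset


@dataclass
class FluencyDataset:
    """Cleaned fluency lists plus participant metadata.

    ``responses`` is a long table of unique canonical tokens per
    (participant, task, timepoint), positions contiguous from 1.  ``scores``
    optionally carries the knowledge-test score and a 1-9 grade ordinal.
    ``cleaning_log`` records every token change or removal, so all
    exclusions are reproducible from the logs alone.
    """

    responses: pd.DataFrame
    scores: pd.DataFrame | None = None
    cleaning_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["participant_id", "task", "timepoint", "position",
                     "action", "original", "result"]))

    def lists(self) -> pd.Series:
        """Ordered token lists keyed by (participant, task, timepoint)."""
        ordered = self.responses.sort_values(_LIST_KEY + ["position"])
        return ordered.groupby(_LIST_KEY)["token"].agg(list)

    def fluency_scores(self) -> pd.Series:
        """Number of (cleaned) responses per participant list."""
        return self.responses.groupby(_LIST_KEY)["token"].size()

    @property
    def participants(self) -> list[str]:
        return sorted(self.responses["participant_id"].unique())

    @property
    def tasks(self) -> list[str]:
        return sorted(self.responses["task"].unique())

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.responses["timepoint"].unique())


def clean_responses(raw: pd.DataFrame, rules: CleaningRules | None = None,
                    scores: pd.DataFrame | None = None) -> FluencyDataset:
    """Normalize tokens and drop intrusions and within-list repetitions.

    Tokens are whitespace-trimmed and case-folded (per ``rules``), mapped
    through the normalization dictionary, exclusion-listed tokens removed,
    and duplicates within one participant's list dropped keeping the
    earliest position.  Every change is recorded in the cleaning log;
    nothing here is fatal.
    """
    rules = rules or CleaningRules()
    raw = validate_fluency_table(raw)
    log_rows: list[dict] = []
    keep = np.ones(len(raw), dtype=bool)
    cleaned_tokens = raw["token"].to_numpy(dtype=object).copy()

    for i, row in enumerate(raw.itertuples(index=False)):
        canon = rules.apply(row.token)
        if canon is None:
            keep[i] = False
            log_rows.append({
                "participant_id": row.participant_id, "task": row.task,
                "timepoint": row.timepoint, "position": row.position,
                "action": "excluded", "original": row.token, "result": ""})
        else:
            if canon != row.token:
                log_rows.append({
                    "participant_id": row.participant_id, "task": row.task,
                    "timepoint": row.timepoint, "position": row.position,
                    "action": "normalized", "original": row.token,
                    "result": canon})
            cleaned_tokens[i] = canon

    out = raw.copy()
    out["token"] = cleaned_tokens
    out = out.loc[keep]

    # within-list duplicates after normalization: keep earliest position
    dup = out.duplicated(subset=_LIST_KEY + ["token"], keep="first")
    for row in out.loc[dup].itertuples(index=False):
        log_rows.append({
            "participant_id": row.participant_id, "task": row.task,
            "timepoint": row.timepoint, "position": row.position,
            "action": "duplicate_removed", "original": row.token,
            "result": ""})
    out = out.loc[~dup].copy()

    out = out.sort_values(_LIST_KEY + ["position"], kind="mergesort")
    out["position"] = out.groupby(_LIST_KEY, sort=False).cumcount() + 1
    out = out.reset_index(drop=True)

    log = pd.DataFrame(log_rows, columns=["participant_id", "task",
                                          "timepoint", "position", "action",
                                          "original", "result"])
    if len(log):
        logger.info("cleaning changed/removed %d responses", len(log))
    return FluencyDataset(responses=out, scores=scores, cleaning_log=log)


def exclude_low_fluency(ds: FluencyDataset,
                        min_responses: int = 3) -> FluencyDataset:
    """Remove participants with any task list shorter than ``min_responses``.

    A participant falling below threshold on one task is removed from all
    tasks and timepoints.  Raises :class:`EmptyResultError` if nobody
    survives.
    """
    if min_responses < 1:
        raise ValueError("min_responses must be >= 1")
    counts = ds.fluency_scores()
    too_short = counts[counts < min_responses]
    excluded = sorted(too_short.index.get_level_values("participant_id").unique())
    if excluded:
        logger.info("excluding %d low-fluency participant(s): %s",
                    len(excluded), ", ".join(excluded))
    mask = ~ds.responses["participant_id"].isin(excluded)
    out = ds.responses.loc[mask].reset_index(drop=True)
    if out.empty:
        raise EmptyResultError("no participants left after low-fluency exclusion")
    scores = ds.scores
    if scores is not None:
        scores = scores.loc[~scores["participant_id"].isin(excluded)]
        scores = scores.reset_index(drop=True)
    log = pd.concat([ds.cleaning_log, pd.DataFrame(
        [{"participant_id": p, "task": "", "timepoint": "", "position": 0,
          "action": "low_fluency_excluded", "original": "", "result": ""}
         for p in excluded])], ignore_index=True) if excluded else ds.cleaning_log
    return FluencyDataset(responses=out, scores=scores, cleaning_log=log)


# ---------------------------------------------------------------------------
# median split


@dataclass(frozen=True)
class GroupAssignment:
    """Result of the median split on knowledge-test scores.

    ``assignments`` maps participant id to ``low``, ``high`` or
    ``excluded_at_median``; scores strictly below the median go low, strictly
    above go high, and median-valued participants belong to neither group so
    the boundary stays well-defined.
    """

    assignments: Mapping[str, str]
    median: float

    @property
    def low(self) -> list[str]:
        return sorted(p for p, g in self.assignments.items() if g == "low")

    @property
    def high(self) -> list[str]:
        return sorted(p for p, g in self.assignments.items() if g == "high")

    @property
    def excluded_at_median(self) -> list[str]:
        return sorted(p for p, g in self.assignments.items()
                      if g == "excluded_at_median")

    def counts(self) -> dict[str, int]:
        return {"low": len(self.low), "high": len(self.high),
                "excluded_at_median": len(self.excluded_at_median)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": list(self.assignments),
             "group": [self.assignments[p] for p in self.assignments]}
        ).sort_values("participant_id").reset_index(drop=True)


def median_split(scores: Mapping[str, float] | pd.Series) -> GroupAssignment:
    """Split participants into low/high knowledge groups at the median score.

    The median is the standard sample median of the supplied (post-exclusion)
    scores.  Participants scoring exactly the median are excluded; with an
    even number of distinct middle values the median falls between scores and
    nobody is dropped.

    Raises
    ------
    FluencyNetError
        Fewer than 2 distinct score values (no split possible).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    values = np.asarray(list(scores.values()), dtype=float)
    if len(values) == 0:
        raise EmptyResultError("no scores to split")
    if len(np.unique(values)) < 2:
        raise IntegrityError("all scores identical: median split impossible")
    med = float(np.median(values))
    assignments = {}
    for pid, s in scores.items():
        if s < med:
            assignments[str(pid)] = "low"
        elif s > med:
            assignments[str(pid)] = "high"
        else:
            assignments[str(pid)] = "excluded_at_median"
    ga = GroupAssignment(assignments=assignments, median=med)
    logger.info("median split at %.2f: low=%d high=%d excluded=%d", med,
                len(ga.low), len(ga.high), len(ga.excluded_at_median))
    return ga


# ---------------------------------------------------------------------------
# binarization


def build_response_matrix(ds: FluencyDataset, task: str, timepoint: str,
                          scope: Iterable[str] | None = None) -> pd.DataFrame:
    """Binary participant x token incidence matrix for one task/timepoint.

    Rows are participants in ``scope`` (default: everyone with responses in
    the cell), columns the sorted union of tokens any scoped participant
    produced; cell (i, j) is 1 iff participant i produced token j.
    """
    sub = ds.responses
    sub = sub[(sub["task"] == task) & (sub["timepoint"] == timepoint)]
    if scope is not None:
        scope = [str(p) for p in scope]
        if not scope:
            raise EmptyResultError("empty participant scope")
        sub = sub[sub["participant_id"].isin(scope)]
        index = sorted(scope)
    else:
        index = sorted(sub["participant_id"].unique())
    if sub.empty:
        raise EmptyResultError(
            f"no responses for task={task!r} timepoint={timepoint!r} in scope")
    mat = pd.crosstab(sub["participant_id"], sub["token"])
    mat = (mat > 0).astype(np.int8)
    mat = mat.reindex(index=index, fill_value=0)
    mat = mat.reindex(columns=sorted(mat.columns))
    mat.index.name = "participant_id"
    mat.columns.name = "token"
    return mat


def frequency_filter(matrix: pd.DataFrame,
                     min_producers: int = 2) -> pd.DataFrame:
    """Drop response types produced by fewer than ``min_producers``
    participants.

    Applied to the overall-sample matrix before any group split, so rare
    idiosyncratic responses never enter the networks.
    """
    if min_producers < 1:
        raise ValueError("min_producers must be >= 1")
    keep = matrix.sum(axis=0) >= min_producers
    out = matrix.loc[:, keep.to_numpy()]
    if out.shape[1] == 0:
        raise EmptyResultError(
            f"no response types produced by >= {min_producers} participants")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("frequency filter dropped %d of %d response types",
                    dropped, matrix.shape[1])
    return out
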