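"""Construct per-class weighted directed networks and agent attributes.

Two network representations of each school class:

* **web**: one-to-one message logs; edge sender→receiver for every ordered
  pair with at least one message, weight = pair message count divided by
  the class's maximum pair count (so the heaviest pair has weight 1).
* **nomination**: sociometric questions; edge ego→alter exists iff the ego
  named the alter in question 1 ("who do you hang out or have contact
  with"), weight = fraction of the four questions naming that alter, hence
  one of {0.25, 0.5, 0.75, 1}.

Step counts are reduced to a physical activity level (PAL): drop days 1
and 7 of each 7-day wave, drop incomplete days and days under 1,000 steps,
and if at least three valid days remain take their mean divided by 10,000.
Participants with fewer than three valid days are imputed from same-sex
classmates (cohort mean as fallback). FAS answers are summed to 0-12.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ClassNetwork",
    "PALRecord",
    "FASRecord",
    "InputError",
    "build_web_network",
    "build_nomination_network",
    "compute_pal",
    "compute_fas",
    "pal_table",
    "fas_table",
    "write_edge_lists",
]

logger = logging.getLogger(__name__)

STEPS_SCALE = 10_000.0
MIN_VALID_STEPS = 1000
MIN_VALID_DAYS = 3


class InputError(ValueError):
    """Raised on malformed message, nomination or questionnaire records."""


@dataclass(frozen=True)
class ClassNetwork:
    """A per-class directed weighted network with its provenance tag."""

    class_id: int
    graph: nx.DiGraph
    source: str  # "web" | "nomination"

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.graph.edges())


@dataclass(frozen=True)
class PALRecord:
    participant_id: int
    pal: float
    n_valid_days: int
    imputed: bool


@dataclass(frozen=True)
class FASRecord:
    participant_id: int
    score: int


def _class_nodes(roster: pd.DataFrame) -> dict[int, np.ndarray]:
    return {
        int(c): g["participant_id"].to_numpy()
        for c, g in roster.groupby("class_id")
    }


def build_web_network(
    messages: pd.DataFrame, roster: pd.DataFrame
) -> dict[int, ClassNetwork]:
    """Per-class networks from one-to-one messages.

    Cross-class or self-directed messages are rejected (counted and
    logged, not fatal). Every roster member is a node; isolates are kept.
    """
    nodes_by_class = _class_nodes(roster)
    class_of = dict(zip(roster["participant_id"], roster["class_id"]))

    ok = messages["sender_id"].map(class_of).eq(messages["class_id"]) & \
        messages["receiver_id"].map(class_of).eq(messages["class_id"]) & \
        (messages["sender_id"] != messages["receiver_id"])
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d cross-class or self-directed messages", n_rejected)
    messages = messages[ok]

    out: dict[int, ClassNetwork] = {}
    counts = messages.groupby(["class_id", "sender_id", "receiver_id"]).size()
    for c, nodes in nodes_by_class.items():
        g = nx.DiGraph()
        g.add_nodes_from(int(v) for v in nodes)
        if c in counts.index.get_level_values(0):
            sub = counts.loc[c]
            mmax = float(sub.max())
            for (i, j), m in sub.items():
                g.add_edge(int(i), int(j), weight=float(m) / mmax)
        else:
            warnings.warn(f"class {c}: no messages; web network is empty")
        out[c] = ClassNetwork(class_id=c, graph=g, source="web")
    return out


def build_nomination_network(
    nominations: pd.DataFrame, roster: pd.DataFrame, n_questions: int = 4
) -> dict[int, ClassNetwork]:
    """Per-class networks from peer nominations.

    Edge ego→alter exists iff the ego nominated the alter in question 1;
    its weight is the number of questions (of ``n_questions``) in which
    the nomination occurred, divided by ``n_questions``.
    """
    if not nominations.empty:
        q = nominations["question"]
        if (q < 1).any() or (q > n_questions).any():
            bad = sorted(q[(q < 1) | (q > n_questions)].unique())
            raise InputError(f"question index out of range 1..{n_questions}: {bad}")
        if (nominations["ego_id"] == nominations["alter_id"]).any():
            raise InputError("self-nomination encountered")

    nodes_by_class = _class_nodes(roster)
    out: dict[int, ClassNetwork] = {}
    q1 = nominations[nominations["question"] == 1]
    n_named = nominations.groupby(["class_id", "ego_id", "alter_id"])["question"].nunique()
    for c, nodes in nodes_by_class.items():
        g = nx.DiGraph()
        g.add_nodes_from(int(v) for v in nodes)
        sub = q1[q1["class_id"] == c]
        for ego, alter in zip(sub["ego_id"], sub["alter_id"]):
            w = int(n_named.loc[(c, ego, alter)]) / float(n_questions)
            g.add_edge(int(ego), int(alter), weight=w)
        out[c] = ClassNetwork(class_id=c, graph=g, source="nomination")
    return out


# ---------------------------------------------------------------------------
# PAL preprocessing


def compute_pal(
    daily_steps: Iterable[float],
    complete: Iterable[bool] | None = None,
    participant_id: int = -1,
) -> PALRecord:
    """Reduce one wave's 7 daily step counts to a PAL record.

    Days 1 and 7 are dropped (never full measurement days); remaining days
    flagged incomplete, missing (NaN), or under 1,000 steps are dropped.
    With >= 3 valid days, PAL = mean(valid steps) / 10,000; otherwise the
    record is returned with ``imputed=True`` and ``pal=nan`` for the
    cohort-level imputation rule in :func:`pal_table` to fill.
    """
    steps = np.asarray(list(daily_steps), dtype=float)
    if steps.size != 7:
        raise InputError(f"expected 7 daily values per wave, got {steps.size}")
    comp = np.ones(7, dtype=bool) if complete is None else np.asarray(list(complete), dtype=bool)
    valid = comp & ~np.isnan(steps) & (steps >= MIN_VALID_STEPS)
    valid[[0, 6]] = False
    n_valid = int(valid.sum())
    if n_valid >= MIN_VALID_DAYS:
        return PALRecord(participant_id, float(steps[valid].mean() / STEPS_SCALE), n_valid, False)
    return PALRecord(participant_id, float("nan"), n_valid, True)


def pal_table(
    steps: pd.DataFrame,
    roster: pd.DataFrame,
    waves: Iterable[int],
) -> pd.DataFrame:
    """Per-participant PAL averaged over ``waves``, with imputation.

    Each wave is reduced with :func:`compute_pal`; a participant's PAL is
    the mean over the requested waves that yielded a valid value.
    Participants with no valid wave are imputed with the mean PAL of
    same-sex classmates (falling back to the cohort mean), mirroring how
    the analysis initializes agents it cannot observe.

    Returns columns participant_id, pal, n_valid_days, imputed.
    """
    waves = list(waves)
    sub = steps[steps["wave"].isin(waves)]
    recs: dict[int, list[PALRecord]] = {}
    for (pid, _w), g in sub.groupby(["participant_id", "wave"]):
        g = g.sort_values("day")
        recs.setdefault(int(pid), []).append(
            compute_pal(g["steps"].to_numpy(), g["complete"].to_numpy(), int(pid))
        )
    rows = []
    for pid in roster["participant_id"]:
        rlist = recs.get(int(pid), [])
        vals = [r.pal for r in rlist if not r.imputed]
        n_valid = sum(r.n_valid_days for r in rlist)
        if vals:
            rows.append((int(pid), float(np.mean(vals)), n_valid, False))
        else:
            rows.append((int(pid), np.nan, n_valid, True))
    tab = pd.DataFrame(rows, columns=["participant_id", "pal", "n_valid_days", "imputed"])
    tab = tab.merge(roster[["participant_id", "class_id", "sex"]], on="participant_id")

    cohort_mean = tab["pal"].mean()
    group_mean = tab.groupby(["class_id", "sex"])["pal"].transform("mean")
    tab["pal"] = tab["pal"].fillna(group_mean).fillna(cohort_mean)
    return tab[["participant_id", "class_id", "sex", "pal", "n_valid_days", "imputed"]]


# ---------------------------------------------------------------------------
# FAS

_FAS_ITEM_MAX = 3


def compute_fas(answers: Iterable[int], participant_id: int = -1) -> FASRecord:
    """Sum the four affluence items into a 0-12 score."""
    a = list(answers)
    if len(a) != 4:
        raise InputError(f"expected 4 FAS items, got {len(a)}")
    for k, v in enumerate(a):
        if not 0 <= int(v) <= _FAS_ITEM_MAX:
            raise InputError(f"FAS item {k + 1} out of range 0..{_FAS_ITEM_MAX}: {v}")
    return FASRecord(participant_id, int(sum(int(v) for v in a)))


def fas_table(fas: pd.DataFrame) -> pd.DataFrame:
    """Per-participant FAS scores from the four-item answer table."""
    items = [c for c in fas.columns if c.startswith("item")]
    scores = [
        compute_fas(row, pid).score
        for pid, row in zip(fas["participant_id"], fas[items].to_numpy())
    ]
    return pd.DataFrame({"participant_id": fas["participant_id"], "fas": scores})


def write_edge_lists(
    networks: Mapping[int, ClassNetwork], out_path
) -> pd.DataFrame:
    """Flatten per-class networks to one CSV edge list (source,target,weight)."""
    rows = [
        (net.class_id, u, v, d["weight"])
        for net in networks.values()
        for u, v, d in net.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["class_id", "source", "target", "weight"])
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
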