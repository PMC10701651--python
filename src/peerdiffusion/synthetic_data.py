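"""Synthetic classroom cohorts for the diffusion analysis.

Generates rosters, one-to-one message logs, peer nominations, daily step
counts and Family Affluence Scale (FAS) answers with the statistical
structure the downstream pipeline assumes: 21 classes of 15+ pupils,
right-skewed per-pair message counts whose class totals fall in a fixed
range, at least one nomination per pupil per sociometric question, daily
steps averaging ~9,200 with a tunable rate of invalid wear days, and a
tunable Jaccard overlap (~0.69 by default) between the message-based and
nomination-based networks.

Both observed networks are modelled as thinnings of a latent per-class
friendship graph: messages concentrate on latent ties (zero-inflated
Dirichlet-multinomial split of a class total), and nominations sample
latent ties with an inclusion probability solved by bisection so the
expected edge-set Jaccard between the two constructed networks matches
``network_overlap_target``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "ConfigurationError",
    "GenerationError",
    "generate_roster",
    "generate_interactions",
    "generate_pal_and_fas",
    "generate_dataset",
]

N_WAVES = 7
N_DAYS = 7


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig field violates an invariant."""


class GenerationError(RuntimeError):
    """Raised when generation is impossible (e.g. a class of one pupil)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: 21 classes of 15-27 pupils
    (~430 total), per-class message totals inside [143, 5301], four
    nomination questions with at least one nominee each, steps averaging
    9,200/day and FAS sums averaging 9.1 on a 0-12 scale.
    """

    n_classes: int = 21
    class_size_range: tuple[int, int] = (15, 27)
    message_total_range: tuple[int, int] = (143, 5301)
    message_dispersion: float = 8.0
    n_questions: int = 4
    nominations_per_question_range: tuple[int, int] = (1, 10)
    network_overlap_target: float = 0.69
    pal_mean_steps: float = 9200.0
    pal_range_steps: tuple[float, float] = (1200.0, 18700.0)
    sex_pal_offset: float = 400.0
    fas_mean: float = 9.1
    invalid_day_rate: float = 0.12
    seed: int = 0
    # latent-structure knobs (not part of the observed-data contract)
    latent_density: float = 0.45
    message_zero_inflation: float = 0.12
    offtie_nomination_rate: float = 0.01
    requestion_overlap: float = 0.25
    pal_between_sd: float = 2600.0
    pal_within_sd: float = 1800.0

    def validate(self) -> None:
        def _interval(name: str, lo, hi, min_lo=None) -> None:
            if lo > hi:
                raise ConfigurationError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
            if min_lo is not None and lo < min_lo:
                raise ConfigurationError(f"{name}: lower bound {lo} is below the minimum {min_lo}")

        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be at least 1")
        _interval("class_size_range", *self.class_size_range, min_lo=15)
        _interval("message_total_range", *self.message_total_range, min_lo=1)
        _interval("nominations_per_question_range", *self.nominations_per_question_range, min_lo=1)
        _interval("pal_range_steps", *self.pal_range_steps)
        if self.pal_range_steps[0] >= self.pal_range_steps[1]:
            raise ConfigurationError("pal_range_steps must be a non-degenerate interval")
        if self.message_dispersion <= 0:
            raise ConfigurationError("message_dispersion must be positive")
        if self.n_questions < 1:
            raise ConfigurationError("n_questions must be at least 1")
        for name in ("network_overlap_target", "invalid_day_rate", "latent_density",
                     "message_zero_inflation", "offtie_nomination_rate", "requestion_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.fas_mean <= 12.0:
            raise ConfigurationError(f"fas_mean must lie in [0, 12], got {self.fas_mean}")


@dataclass
class SyntheticDataset:
    """A generated cohort plus the latent truth used to generate it."""

    roster: pd.DataFrame
    messages: pd.DataFrame
    nominations: pd.DataFrame
    steps: pd.DataFrame
    fas: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write the five tables as UTF-8 CSV and the truth as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("roster", "messages", "nominations", "steps", "fas"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        serializable = {
            k: v for k, v in self.truth.items() if k != "latent_edges"
        }
        serializable["latent_edges"] = {
            str(c): [list(map(int, e)) for e in edges]
            for c, edges in self.truth.get("latent_edges", {}).items()
        }
        (out / "truth.json").write_text(json.dumps(serializable, indent=1, default=float))

    @classmethod
    def read(cls, in_dir: str | Path) -> "SyntheticDataset":
        p = Path(in_dir)
        tables = {name: pd.read_csv(p / f"{name}.csv") for name in
                  ("roster", "messages", "nominations", "steps", "fas")}
        truth_path = p / "truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
        return cls(truth=truth, **tables)


# ---------------------------------------------------------------------------
# roster


def generate_roster(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw class sizes and pupil attributes.

    Returns a table with columns participant_id, class_id, sex ('F'/'M'),
    age (integer years, 8-15). Sex is assigned ~50/50 within each class.
    """
    config.validate()
    lo, hi = config.class_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_classes)
    rows = []
    pid = 0
    for c, size in enumerate(sizes, start=1):
        sexes = np.array(["F", "M"])[rng.permutation(np.arange(size) % 2)]
        # classmates share a school year; ages span two adjacent years
        base_age = int(rng.integers(8, 15))
        ages = base_age + rng.integers(0, 2, size=size)
        for k in range(size):
            rows.append((pid, c, sexes[k], int(ages[k])))
            pid += 1
    return pd.DataFrame(rows, columns=["participant_id", "class_id", "sex", "age"])


# ---------------------------------------------------------------------------
# interactions


def _latent_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean adjacency of the latent friendship graph.

    Every pupil is guaranteed at least one latent friend so the
    minimum-one-nomination rule never has to fall outside the graph.
    """
    adj = rng.random((n, n)) < density
    adj = np.triu(adj, k=1)
    adj = adj | adj.T
    for i in range(n):
        if not adj[i].any():
            j = int(rng.integers(0, n - 1))
            j = j + (j >= i)
            adj[i, j] = adj[j, i] = True
    return adj

def _expected_jaccard(a: float, b: float, q: float, eps: float) -> float:
    """Expected edge-set Jaccard of two independent thinnings of latent ties.

    a: P(web edge | latent directed tie); b: P(nomination | latent tie);
    q: latent directed-tie density; eps: off-tie nomination probability.
    """
    shared = q * a * b
    union = q * a + q * b - shared + (1.0 - q) * eps
    return shared / union if union > 0 else 0.0


def _solve_nomination_prob(a: float, q: float, eps: float, target: float) -> float:
    """Bisection for the latent-tie nomination probability hitting `target`."""
    lo, hi = 1e-6, 1.0
    if _expected_jaccard(a, hi, q, eps) <= target:
        return hi  # target unreachable; saturate (J is increasing in b)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_jaccard(a, mid, q, eps) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_interactions(
    roster: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Draw message events and nomination events for every class.

    Returns (messages, nominations, truth). Messages are one row per
    message (sender_id, receiver_id, class_id); nominations one row per
    (ego_id, alter_id, class_id, question).
    """
    config.validate()
    if roster.empty:
        raise GenerationError("roster is empty")

    a = 1.0 - config.message_zero_inflation
    b = _solve_nomination_prob(
        a, config.latent_density, config.offtie_nomination_rate, config.network_overlap_target
    )
    alpha = 1.0 / config.message_dispersion

    msg_rows: list[tuple[int, int, int]] = []
    nom_rows: list[tuple[int, int, int, int]] = []
    latent_edges: dict[int, list[tuple[int, int]]] = {}

    lo_t, hi_t = config.message_total_range
    nom_lo, nom_hi = config.nominations_per_question_range

    for c, group in roster.groupby("class_id"):
        ids = group["participant_id"].to_numpy()
        n = len(ids)
        if n < 2:
            raise GenerationError(f"class {c} has fewer than 2 pupils")
        adj = _latent_graph(n, config.latent_density, rng)
        latent_edges[int(c)] = [
            (int(ids[i]), int(ids[j])) for i in range(n) for j in range(n) if adj[i, j] and i < j
        ]

        # -- messages: class total in range, split over active directed ties
        di, dj = np.nonzero(adj)  # all directed latent ties (adj symmetric)
        active = rng.random(di.size) < a
        # class total right-skewed across classes: log-uniform inside the range
        total = int(np.exp(rng.uniform(np.log(lo_t), np.log(hi_t))))
        if active.sum() == 0:
            active[rng.integers(0, di.size)] = True
        act_idx = np.nonzero(active)[0]
        if act_idx.size > total:  # rare: tiny class total; keep one message per kept tie
            act_idx = rng.choice(act_idx, size=total, replace=False)
        weights = rng.gamma(alpha, 1.0, size=act_idx.size)
        weights = np.maximum(weights, 1e-12)
        # every active tie carries >= 1 message so the web edge set equals
        # the active latent ties (the overlap bisection assumes this)
        counts = 1 + rng.multinomial(total - act_idx.size, weights / weights.sum())
        for (i, j), cnt in zip(zip(di[act_idx], dj[act_idx]), counts):
            msg_rows.extend([(int(ids[i]), int(ids[j]), int(c))] * int(cnt))

        # -- nominations: question 1 samples latent ties with prob b
        for ego_pos in range(n):
            friends = np.nonzero(adj[ego_pos])[0]
            others = np.array([k for k in range(n) if k != ego_pos and not adj[ego_pos, k]])
            take = friends[rng.random(friends.size) < b]
            if others.size:
                take = np.concatenate(
                    [take, others[rng.random(others.size) < config.offtie_nomination_rate]]
                )
            if take.size < nom_lo:
                pool = np.setdiff1d(friends, take)
                if pool.size < nom_lo - take.size:
                    pool = np.setdiff1d(np.delete(np.arange(n), ego_pos), take)
                extra = rng.choice(pool, size=nom_lo - take.size, replace=False)
                take = np.concatenate([take, extra])
            if take.size > nom_hi:
                take = rng.choice(take, size=nom_hi, replace=False)
            q1_set = set(int(t) for t in take)
            nom_rows.extend((int(ids[ego_pos]), int(ids[t]), int(c), 1) for t in sorted(q1_set))

            # questions 2..N: correlated re-nominations of the q1 set
            for q in range(2, config.n_questions + 1):
                re = [t for t in sorted(q1_set) if rng.random() < config.requestion_overlap]
                if len(re) < nom_lo:
                    pool = np.setdiff1d(np.delete(np.arange(n), ego_pos), np.array(re, dtype=int))
                    extra = rng.choice(pool, size=nom_lo - len(re), replace=False)
                    re.extend(int(e) for e in extra)
                if len(re) > nom_hi:
                    re = [int(x) for x in rng.choice(re, size=nom_hi, replace=False)]
                nom_rows.extend((int(ids[ego_pos]), int(ids[t]), int(c), q) for t in re)

    messages = pd.DataFrame(msg_rows, columns=["sender_id", "receiver_id", "class_id"])
    nominations = pd.DataFrame(nom_rows, columns=["ego_id", "alter_id", "class_id", "question"])
    truth = {
        "latent_edges": latent_edges,
        "nomination_tie_prob": float(b),
        "message_tie_prob": float(a),
        "expected_jaccard": _expected_jaccard(
            a, b, config.latent_density, config.offtie_nomination_rate
        ),
    }
    return messages, nominations, truth


# ---------------------------------------------------------------------------
# steps and FAS


def generate_pal_and_fas(
    roster: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Draw 7 waves x 7 days of step counts and 4 FAS items per pupil.

    Steps: a per-pupil baseline around ``pal_mean_steps`` (sex-offset
    ``sex_pal_offset`` between boys and girls), daily noise, and a fraction
    ``invalid_day_rate`` of days that are invalid — half flagged incomplete
    (<24h wear), half with a sub-1000 step count.

    FAS: four items on 0-3 drawn binomially so the 0-12 sum averages
    ``fas_mean``.
    """
    config.validate()
    if roster.empty:
        raise GenerationError("roster is empty")
    n = len(roster)
    offset = np.where(roster["sex"].to_numpy() == "M", 0.5, -0.5) * config.sex_pal_offset
    lo, hi = config.pal_range_steps
    baseline = np.clip(
        rng.normal(config.pal_mean_steps + offset, config.pal_between_sd),
        lo, hi,
    )

    pids = roster["participant_id"].to_numpy()
    rows = []
    for idx in range(n):
        daily = rng.normal(baseline[idx], config.pal_within_sd, size=(N_WAVES, N_DAYS))
        daily = np.clip(np.round(daily), 0, None).astype(int)
        invalid = rng.random((N_WAVES, N_DAYS)) < config.invalid_day_rate
        incomplete = invalid & (rng.random((N_WAVES, N_DAYS)) < 0.5)
        lowstep = invalid & ~incomplete
        daily[lowstep] = rng.integers(0, 1000, size=int(lowstep.sum()))
        # invalid days must actually fail a filter; days below 1000 by chance are fine
        daily[~invalid & (daily < 1000)] = 1000
        for w in range(N_WAVES):
            for d in range(N_DAYS):
                rows.append(
                    (int(pids[idx]), w + 1, d + 1, int(daily[w, d]), not bool(incomplete[w, d]))
                )
    steps = pd.DataFrame(rows, columns=["participant_id", "wave", "day", "steps", "complete"])

    p_item = np.clip(config.fas_mean / 12.0, 0.0, 1.0)
    items = rng.binomial(3, p_item, size=(n, 4))
    fas = pd.DataFrame(
        {"participant_id": pids, **{f"item{k + 1}": items[:, k] for k in range(4)}}
    )
    truth = {"baseline_steps": {int(p): float(bse) for p, bse in zip(pids, baseline)}}
    return steps, fas, truth


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete cohort from one seed.

    `seed` overrides `config.seed` when given; identical seeds yield
    byte-identical tables.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roster = generate_roster(config, rng)
    messages, nominations, truth_net = generate_interactions(roster, config, rng)
    steps, fas, truth_pal = generate_pal_and_fas(roster, config, rng)
    truth = {
        **truth_net,
        **truth_pal,
        "config": asdict(config),
        "seed": int(config.seed if seed is None else seed),
        "overlap_target": config.network_overlap_target,
    }
    return SyntheticDataset(
        roster=roster, messages=messages, nominations=nominations,
        steps=steps, fas=fas, truth=truth,
    )
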