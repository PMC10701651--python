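"""Threshold agent-based model of physical-activity diffusion.

Each agent carries a physical activity level (PAL, daily steps / 10,000)
and a socioeconomic score (FAS, 0-12). Once per simulated day every agent
synchronously evaluates a combined influence

    C_i = (1 - lambda_env) * S_i + lambda_env * E_i

where S_i is the weighted mean PAL of the agent's influencers (rows of a
normalized influence matrix derived from the class network) and E_i is a
socioeconomic target, E_i = mean(PAL_0) * FAS_i / mean(FAS_0) clipped to
the PAL bounds. Agents with no influencers use C_i = E_i. If the gap
|C_i - PAL_i| strictly exceeds the change threshold T_PAL, the agent
multiplies its PAL by (1 +/- I_PAL) toward C_i, clipped to the bounds;
otherwise it keeps its PAL. The update is deterministic given the state:
run-to-run variation comes from parameter uncertainty and initial
sampling, not from per-step noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_builder import ClassNetwork

__all__ = [
    "AgentState",
    "Population",
    "ModelParams",
    "InfluenceMatrix",
    "Trajectory",
    "build_influence_matrix",
    "environment_target",
    "step",
    "run_simulation",
    "run_to_steady",
    "detect_steady_state",
]

ORIENTATIONS = ("received", "sent")


@dataclass(frozen=True)
class AgentState:
    """One participant's simulated state."""

    id: int
    class_id: int
    pal: float
    fas: int
    influential: bool = False


@dataclass
class Population:
    """Vectorized agent states (one cohort; classes simulated jointly)."""

    ids: np.ndarray
    class_ids: np.ndarray
    pal: np.ndarray
    fas: np.ndarray
    influential: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.pal = np.asarray(self.pal, dtype=float)
        self.fas = np.asarray(self.fas, dtype=float)
        self.influential = np.asarray(self.influential, dtype=bool)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._classes = np.unique(self.class_ids)
        self._codes = np.searchsorted(self._classes, self.class_ids)

    @classmethod
    def from_agents(cls, agents: Sequence[AgentState]) -> "Population":
        return cls(
            ids=[a.id for a in agents],
            class_ids=[a.class_id for a in agents],
            pal=[a.pal for a in agents],
            fas=[a.fas for a in agents],
            influential=[a.influential for a in agents],
        )

    @classmethod
    def from_tables(cls, roster: pd.DataFrame, pal: pd.DataFrame, fas: pd.DataFrame) -> "Population":
        df = roster.merge(pal[["participant_id", "pal"]], on="participant_id") \
                   .merge(fas[["participant_id", "fas"]], on="participant_id")
        return cls(
            ids=df["participant_id"].to_numpy(),
            class_ids=df["class_id"].to_numpy(),
            pal=df["pal"].to_numpy(),
            fas=df["fas"].to_numpy(),
            influential=np.zeros(len(df), dtype=bool),
        )

    def agents(self) -> list[AgentState]:
        return [
            AgentState(int(i), int(c), float(p), int(f), bool(b))
            for i, c, p, f, b in zip(self.ids, self.class_ids, self.pal, self.fas, self.influential)
        ]

    def index_of(self, participant_id: int) -> int:
        return self._index[int(participant_id)]

    @property
    def classes(self) -> np.ndarray:
        return self._classes

    @property
    def class_codes(self) -> np.ndarray:
        return self._codes

    def class_means(self, pal: np.ndarray | None = None) -> np.ndarray:
        """Mean PAL per class (sorted by class id); columns supported."""
        p = self.pal if pal is None else pal
        counts = np.bincount(self._codes, minlength=len(self._classes)).astype(float)
        if p.ndim == 1:
            sums = np.bincount(self._codes, weights=p, minlength=len(self._classes))
            return sums / counts
        ind = np.zeros((len(self._classes), p.shape[0]))
        ind[self._codes, np.arange(p.shape[0])] = 1.0
        return (ind @ p) / counts[:, None]

    def with_pal(self, pal: np.ndarray) -> "Population":
        return Population(self.ids, self.class_ids, np.asarray(pal, float).copy(),
                          self.fas, self.influential)


@dataclass(frozen=True)
class ModelParams:
    """Tunable and fixed constants of the diffusion model.

    t_pal and i_pal are the two calibrated parameters; lambda_env, the PAL
    bounds and the influence orientation are fixed design constants.
    """

    t_pal: float
    i_pal: float
    lambda_env: float = 0.2
    pal_bounds: tuple[float, float] = (0.1, 2.0)
    influence_orientation: str = "received"

    def __post_init__(self):
        if self.t_pal < 0:
            raise ValueError(f"t_pal must be non-negative, got {self.t_pal}")
        if not 0 <= self.i_pal < 1:
            raise ValueError(f"i_pal must lie in [0, 1), got {self.i_pal}")
        if not 0 <= self.lambda_env <= 1:
            raise ValueError(f"lambda_env must lie in [0, 1], got {self.lambda_env}")
        if self.pal_bounds[0] >= self.pal_bounds[1]:
            raise ValueError("pal_bounds must be a non-degenerate interval")
        if self.influence_orientation not in ORIENTATIONS:
            raise ValueError(f"influence_orientation must be one of {ORIENTATIONS}")


@dataclass
class InfluenceMatrix:
    """Row-normalized who-influences-whom weights.

    ``w[i, j]`` is the weight agent ``i`` puts on agent ``j``; non-isolated
    rows sum to 1, isolated agents (no influencers) are flagged and follow
    environment-only dynamics.
    """

    w: np.ndarray
    isolated: np.ndarray


def build_influence_matrix(
    networks: Mapping[int, ClassNetwork] | ClassNetwork,
    population: Population,
    params: ModelParams,
) -> InfluenceMatrix:
    """Derive the influence matrix from the stored class networks.

    Stored edges are data-directed (web: sender→receiver; nomination:
    ego→nominated alter). Under the default ``received`` orientation the
    peers salient to an ego influence the ego: a message *sender* influences
    the receiver, and a *nominated alter* influences the nominating ego.
    The ``sent`` orientation flips both.
    """
    nets = {networks.class_id: networks} if isinstance(networks, ClassNetwork) else networks
    n = len(population.ids)
    w = np.zeros((n, n))
    for net in nets.values():
        for u, v, d in net.graph.edges(data=True):
            iu, iv = population.index_of(u), population.index_of(v)
            if net.source == "web":
                recv, src = (iv, iu) if params.influence_orientation == "received" else (iu, iv)
            else:  # nomination: ego u names alter v; v is salient to u
                recv, src = (iu, iv) if params.influence_orientation == "received" else (iv, iu)
            w[recv, src] += float(d["weight"])
    rowsums = w.sum(axis=1)
    isolated = rowsums == 0
    w[~isolated] /= rowsums[~isolated, None]
    return InfluenceMatrix(w=w, isolated=isolated)


def environment_target(
    population: Population,
    params: ModelParams,
    pal0_mean: float | None = None,
    fas0_mean: float | None = None,
) -> np.ndarray:
    """E_i = mean(PAL_0) * FAS_i / mean(FAS_0), clipped to the PAL bounds.

    The anchors default to the population's own initial means but are
    normally fixed at the wave-1 cohort means so that calibration and
    intervention runs share one environment.
    """
    p0 = float(np.mean(population.pal)) if pal0_mean is None else float(pal0_mean)
    f0 = float(np.mean(population.fas)) if fas0_mean is None else float(fas0_mean)
    if f0 <= 0:
        raise ValueError("mean FAS anchor must be positive")
    return np.clip(p0 * population.fas / f0, *params.pal_bounds)


def _step_pal(
    pal: np.ndarray,
    w: np.ndarray,
    isolated: np.ndarray,
    env: np.ndarray,
    t_pal,
    i_pal,
    lambda_env: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """One synchronous day update; ``pal`` may be (n,) or (n, k) columns.

    t_pal / i_pal may be scalars or per-column arrays (batched sweeps).
    """
    social = w @ pal
    env_col = env if pal.ndim == 1 else env[:, None]
    combined = (1.0 - lambda_env) * social + lambda_env * env_col
    if pal.ndim == 1:
        combined[isolated] = env[isolated]
    else:
        combined[isolated, :] = env_col[isolated]
    delta = combined - pal
    # strict threshold, padded by an epsilon so float roundoff in the
    # weighted mean cannot trigger a change of a homogeneous cohort
    move = np.abs(delta) > np.asarray(t_pal) + 1e-12
    stepped = np.clip(pal * (1.0 + np.sign(delta) * i_pal), bounds[0], bounds[1])
    return np.where(move, stepped, pal)


def step(states: Population, W: InfluenceMatrix, params: ModelParams,
         env: np.ndarray | None = None) -> Population:
    """Advance every agent one day, synchronously."""
    e = environment_target(states, params) if env is None else env
    new = _step_pal(states.pal, W.w, W.isolated, e, params.t_pal, params.i_pal,
                    params.lambda_env, params.pal_bounds)
    return states.with_pal(new)


@dataclass
class Trajectory:
    """Daily per-class mean PAL (and optional agent snapshots)."""

    class_ids: np.ndarray
    class_means: np.ndarray  # (n_days+1, n_classes)
    cohort_mean: np.ndarray  # (n_days+1,)
    snapshots: np.ndarray | None = None  # (n_days+1, n_agents) if recorded

    @property
    def n_days(self) -> int:
        return self.class_means.shape[0] - 1


def run_simulation(
    states: Population,
    W: InfluenceMatrix,
    params: ModelParams,
    n_days: int,
    env: np.ndarray | None = None,
    record_agents: bool = False,
) -> Trajectory:
    """Iterate the daily update ``n_days`` times, recording class means.

    Day 0 is the input snapshot; ``n_days=0`` returns it alone.
    """
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    e = environment_target(states, params) if env is None else env
    pal = states.pal.copy()
    means = np.empty((n_days + 1, len(states.classes)))
    cohort = np.empty(n_days + 1)
    snaps = np.empty((n_days + 1, pal.size)) if record_agents else None
    means[0] = states.class_means(pal)
    cohort[0] = pal.mean()
    if record_agents:
        snaps[0] = pal
    for d in range(1, n_days + 1):
        pal = _step_pal(pal, W.w, W.isolated, e, params.t_pal, params.i_pal,
                        params.lambda_env, params.pal_bounds)
        means[d] = states.class_means(pal)
        cohort[d] = pal.mean()
        if record_agents:
            snaps[d] = pal
    return Trajectory(states.classes.copy(), means, cohort, snaps)


def run_to_steady(
    states: Population,
    W: InfluenceMatrix,
    params: ModelParams,
    env: np.ndarray | None = None,
    tol: float = 1e-4,
    window: int = 10,
    max_days: int = 500,
) -> tuple[Population, int, bool]:
    """Run until every class mean changes < ``tol`` for ``window`` days.

    Returns (final population, days simulated, converged flag); a run that
    hits ``max_days`` without settling is returned unconverged.
    """
    e = environment_target(states, params) if env is None else env
    pal = states.pal.copy()
    prev = states.class_means(pal)
    quiet = 0
    for d in range(1, max_days + 1):
        pal = _step_pal(pal, W.w, W.isolated, e, params.t_pal, params.i_pal,
                        params.lambda_env, params.pal_bounds)
        cur = states.class_means(pal)
        quiet = quiet + 1 if np.abs(cur - prev).max() < tol else 0
        prev = cur
        if quiet >= window:
            return states.with_pal(pal), d, True
    return states.with_pal(pal), max_days, False


def detect_steady_state(traj: Trajectory, tol: float = 1e-4, window: int = 10) -> int | None:
    """First day d such that all class-mean changes on days d+1..d+window < tol."""
    if traj.class_means.shape[0] == 0:
        raise ValueError("trajectory is empty")
    if window <= 0:
        return 0
    diffs = np.abs(np.diff(traj.class_means, axis=0)).max(axis=1)  # change at day t = diffs[t-1]
    if diffs.size < window:
        return None
    ok = diffs < tol
    csum = np.convolve(ok.astype(int), np.ones(window, dtype=int), mode="valid")
    hits = np.nonzero(csum == window)[0]
    return int(hits[0]) if hits.size else None
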