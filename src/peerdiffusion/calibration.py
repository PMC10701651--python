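"""Grid-search calibration of the two diffusion parameters.

The change threshold T_PAL and change magnitude I_PAL are calibrated by
simulating every point of a parameter lattice to steady state from
initial PALs resampled (by sex, with replacement) from the wave-1
distribution, and scoring each point by the sum of squared errors between
the simulated steady-state class means and observed per-class mean PALs
at three year points (waves 2-3, wave 4, waves 5-7). The 100 best-fitting
combinations are retained as the parameter-uncertainty ensemble that all
intervention simulations reuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .abm_core import InfluenceMatrix, ModelParams, Population, _step_pal
from .network_builder import pal_table

__all__ = [
    "GridSpec",
    "ObservationSet",
    "CalibrationResult",
    "CalibrationError",
    "observed_class_means",
    "sample_initial_pal",
    "evaluate_sse",
    "grid_search",
    "YEAR_WAVES",
]

YEAR_WAVES = {"year1": (2, 3), "year2": (4,), "year3": (5, 6, 7)}
N_RETAIN = 100


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Parameter lattice; defaults span frozen (large T) to fast drift."""

    t_min: float = 0.0
    t_max: float = 0.30
    t_step: float = 0.01
    i_min: float = 0.0
    i_max: float = 0.05
    i_step: float = 0.001

    def t_values(self) -> np.ndarray:
        return np.round(np.arange(self.t_min, self.t_max + self.t_step / 2, self.t_step), 10)

    def i_values(self) -> np.ndarray:
        return np.round(np.arange(self.i_min, self.i_max + self.i_step / 2, self.i_step), 10)

    def points(self) -> np.ndarray:
        """(G, 2) array of (t_pal, i_pal) lattice points."""
        tv, iv = np.meshgrid(self.t_values(), self.i_values(), indexing="ij")
        return np.column_stack([tv.ravel(), iv.ravel()])


@dataclass(frozen=True)
class ObservationSet:
    """Observed per-class mean PAL at the three calibration year points."""

    class_ids: np.ndarray
    means: np.ndarray  # (n_classes, 3) columns year1, year2, year3

    def __post_init__(self):
        if (np.asarray(self.means) <= 0).any():
            raise CalibrationError("observed mean PALs must be positive")


def observed_class_means(steps: pd.DataFrame, roster: pd.DataFrame) -> ObservationSet:
    """Reduce the step table to per-class observed means per year point."""
    classes = np.sort(roster["class_id"].unique())
    cols = []
    for waves in YEAR_WAVES.values():
        tab = pal_table(steps, roster, waves)
        cols.append(tab.groupby("class_id")["pal"].mean().reindex(classes).to_numpy())
    return ObservationSet(class_ids=classes, means=np.column_stack(cols))


def sample_initial_pal(
    w1_pal: pd.DataFrame,
    roster: pd.DataFrame,
    rng: np.random.Generator,
    size: int = 1,
    by_class: bool = True,
) -> np.ndarray:
    """Initial PAL per agent, resampled from the wave-1 distribution.

    Draws with replacement from the wave-1 PALs of same-sex classmates
    (``by_class=True``, the default: the model is calibrated against
    per-class observations, so the initialization must preserve the
    between-class PAL structure wave 1 exhibits) or of all same-sex
    participants (``by_class=False``). An empty stratum falls back to the
    sex stratum and then to the pooled distribution with a warning.
    Returns shape (n_agents,) when ``size`` is 1, else (n_agents, size)
    independent draws.
    """
    tab = w1_pal
    for col in ("sex", "class_id"):
        if col not in tab.columns:
            tab = tab.merge(roster[["participant_id", col]], on="participant_id", how="right")
    pooled = tab["pal"].dropna().to_numpy()
    if pooled.size == 0:
        raise CalibrationError("no wave-1 PAL values to sample from")
    out = np.empty((len(roster), size))
    keys = ["class_id", "sex"] if by_class else ["sex"]
    for group, members in roster.groupby(keys):
        mask = np.ones(len(roster), dtype=bool)
        for col, val in zip(keys, group):
            mask &= (roster[col] == val).to_numpy()
        sel = pd.Series(True, index=tab.index)
        for col, val in zip(keys, group):
            sel &= tab[col] == val
        stratum = tab.loc[sel, "pal"].dropna().to_numpy()
        if stratum.size == 0:
            sex = group[-1]
            stratum = tab.loc[tab["sex"] == sex, "pal"].dropna().to_numpy()
            if stratum.size == 0:
                warnings.warn(
                    f"empty wave-1 PAL stratum for sex {sex!r}; using pooled distribution"
                )
                stratum = pooled
            else:
                warnings.warn(
                    f"empty wave-1 PAL stratum {group}; falling back to the sex stratum"
                )
        out[mask] = rng.choice(stratum, size=(int(mask.sum()), size), replace=True)
    return out[:, 0] if size == 1 else out


def evaluate_sse(simulated: np.ndarray, observed: ObservationSet,
                 class_ids: np.ndarray | None = None) -> float:
    """Sum over classes and the three year points of (sim - obs)^2.

    ``simulated`` holds one steady-state mean per class — the model's
    steady state is compared against all three year points — or an
    explicit (n_classes, 3) array of per-year values.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.ndim == 1:
        sim = sim[:, None]
    ids = observed.class_ids if class_ids is None else np.asarray(class_ids)
    if sim.shape[0] != observed.class_ids.shape[0] or not np.array_equal(
        np.sort(ids), np.sort(observed.class_ids)
    ):
        raise CalibrationError("simulated and observed class sets do not match")
    order = np.argsort(ids)
    obs_order = np.argsort(observed.class_ids)
    diff = sim[order] - observed.means[obs_order]
    return float(np.sum(diff**2))


@dataclass
class CalibrationResult:
    """All grid points scored and the retained best-fitting ensemble."""

    table: pd.DataFrame  # columns t_pal, i_pal, sse, capped; sorted by sse
    grid: GridSpec
    seed: int
    n_retain: int = N_RETAIN

    @property
    def retained(self) -> pd.DataFrame:
        return self.table.head(self.n_retain)

    def ensemble_params(self, base: ModelParams) -> list[ModelParams]:
        return [
            replace(base, t_pal=float(r.t_pal), i_pal=float(r.i_pal))
            for r in self.retained.itertuples()
        ]

    def centroid(self) -> tuple[float, float]:
        """Inverse-SSE-weighted centroid of the retained ensemble."""
        r = self.retained
        w = 1.0 / (r["sse"].to_numpy() + 1e-12)
        w = w / w.sum()
        return float(w @ r["t_pal"].to_numpy()), float(w @ r["i_pal"].to_numpy())


def _batched_steady(
    pal0: np.ndarray,  # (n, k)
    W: InfluenceMatrix,
    t_col: np.ndarray,  # (k,)
    i_col: np.ndarray,  # (k,)
    env: np.ndarray,
    params: ModelParams,
    pop: Population,
    tol: float,
    window: int,
    max_days: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run k column-simulations jointly to steady state.

    Returns (class_means (C, k), converged (k,)). Columns share the same
    network and environment but have per-column (T_PAL, I_PAL).
    """
    pal = pal0.copy()
    prev = pop.class_means(pal)
    quiet = np.zeros(pal.shape[1], dtype=int)
    for _ in range(max_days):
        pal = _step_pal(pal, W.w, W.isolated, env, t_col, i_col,
                        params.lambda_env, params.pal_bounds)
        cur = pop.class_means(pal)
        moved = np.abs(cur - prev).max(axis=0) >= tol
        quiet = np.where(moved, 0, quiet + 1)
        prev = cur
        if (quiet >= window).all():
            break
    return prev, quiet >= window


def grid_search(
    W: InfluenceMatrix,
    population: Population,
    w1_pal: pd.DataFrame,
    roster: pd.DataFrame,
    observations: ObservationSet,
    grid: GridSpec | None = None,
    base_params: ModelParams | None = None,
    env: np.ndarray | None = None,
    replicates: int = 3,
    n_retain: int = N_RETAIN,
    seed: int = 0,
    tol: float = 1e-4,
    window: int = 10,
    max_days: int = 500,
    chunk: int = 512,
) -> CalibrationResult:
    """Score every lattice point by steady-state SSE; retain the best.

    Each point is simulated from ``replicates`` initial-PAL draws (one
    common set of draws across points — common random numbers) and scored
    by the mean SSE. Deterministic given ``seed``. Points that hit
    ``max_days`` without settling are scored at their day-cap state and
    flagged ``capped``.
    """
    grid = grid or GridSpec()
    base_params = base_params or ModelParams(t_pal=0.0, i_pal=0.0)
    pts = grid.points()
    if pts.shape[0] == 0:
        raise CalibrationError("empty parameter lattice")
    if pts.shape[0] < n_retain:
        warnings.warn(
            f"lattice has {pts.shape[0]} points; fewer than the {n_retain} requested "
            "for the retained ensemble"
        )
    rng = np.random.default_rng(seed)
    init = sample_initial_pal(w1_pal, roster, rng, size=replicates)  # (n, R)
    if init.ndim == 1:
        init = init[:, None]
    if env is None:
        env = np.clip(
            float(np.nanmean(w1_pal["pal"])) * population.fas / float(np.mean(population.fas)),
            *base_params.pal_bounds,
        )

    n = init.shape[0]
    R = replicates
    sses = np.empty(pts.shape[0])
    capped = np.zeros(pts.shape[0], dtype=bool)
    obs_order = np.argsort(observations.class_ids)
    obs = observations.means[obs_order]  # aligned to sorted class ids = Population.classes
    if not np.array_equal(np.sort(observations.class_ids), population.classes):
        raise CalibrationError("observation classes do not match the population")

    for start in range(0, pts.shape[0], chunk):
        block = pts[start:start + chunk]
        k = block.shape[0] * R
        pal0 = np.repeat(init[:, None, :], block.shape[0], axis=1).reshape(n, k)
        t_col = np.repeat(block[:, 0], R)
        i_col = np.repeat(block[:, 1], R)
        means, conv = _batched_steady(pal0, W, t_col, i_col, env, base_params,
                                      population, tol, window, max_days)
        # means: (C, k) -> per point mean SSE over replicates
        diff = means[:, :, None] - obs[:, None, :]  # (C, k, 3)
        sse_cols = np.sum(diff**2, axis=(0, 2))  # (k,)
        sses[start:start + block.shape[0]] = sse_cols.reshape(block.shape[0], R).mean(axis=1)
        capped[start:start + block.shape[0]] = ~conv.reshape(block.shape[0], R).all(axis=1)

    table = pd.DataFrame(
        {"t_pal": pts[:, 0], "i_pal": pts[:, 1], "sse": sses, "capped": capped}
    ).sort_values(["sse", "t_pal", "i_pal"], kind="mergesort").reset_index(drop=True)
    return CalibrationResult(table=table, grid=grid, seed=seed, n_retain=n_retain)
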