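"""Individual-based coevolution of helper targets and coordination.

Each generation, groups of ``n = l*m`` cells are grown from ``l``
founders; every cell inherits its founder's two heritable traits: the
target helper proportion ``q`` and the coordination level ``s``. Cells
then specialize:

1. **Coordination network.** Each cell independently opens a one-way
   observation link to every other group member with probability equal
   to its own ``s`` (the receiver pays to observe; the sender is
   passive). Under ``own_lineage`` scope only clone-mates can be
   observed.
2. **Sequential resolution.** All cells start as intended
   reproductives. Cells are visited once each, in a uniformly random
   order; a visited cell compares the current fraction of intended
   helpers among the senders it observes with its own ``q`` and becomes
   an intended helper when the observed fraction falls short of the
   target (ties go to reproductive). A cell observing nobody falls back
   to pure phenotypic noise: helper with probability ``q``.
3. **Fecundity.** A helper has fecundity 0; a reproductive has
   ``(1 - cost(s)) * (1 - eps + eps * P)`` where ``P`` is the realized
   helper fraction of the whole group and ``cost(s) = theta*(1 - e^-5s)``
   by default (decelerating: the machinery is expensive to build,
   cheap to extend).
4. **Global competition.** The next generation's founders are drawn
   multinomially from the whole population in proportion to fecundity,
   then each trait mutates independently (probability ``p_mut``, normal
   step of SD ``mut_sd``, clamped to [0, 1]).

With ``s = 0`` everywhere this reduces exactly to the fully random
mechanism of the analytical layer; with ``s = 1`` in a clonal group the
realized helper fraction lands within ``1/n`` of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import ModelParams, _check_proportion

__all__ = [
    "Genotype",
    "SimConfig",
    "GroupBatch",
    "Trajectory",
    "ExperimentResult",
    "VarianceRatioReport",
    "coordination_cost",
    "grow_groups",
    "build_links",
    "resolve_phenotypes",
    "group_fecundities",
    "next_generation",
    "mutate",
    "run_replicate",
    "run_experiment",
    "variability_test",
]

COST_SHAPES = ("decelerating", "linear", "accelerating")
SCOPES = ("whole_group", "own_lineage")


@dataclass(frozen=True)
class Genotype:
    """One founder's heritable traits."""

    q: float  # target helper proportion
    s: float  # coordination level

    def __post_init__(self) -> None:
        _check_proportion("q", self.q)
        _check_proportion("s", self.s)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one evolutionary run.

    Defaults mirror the reference study conditions: populations of about
    10^4 cells evolving for 10^5 generations, 10 replicates, per-trait
    mutation probability 0.01 with normal steps of SD 0.1 clamped to
    [0, 1], summaries averaged over the final 10% of generations, and
    coordination starting absent (``init_s = 0``) so that it must evolve
    de novo.
    """

    params: ModelParams
    target_pop_size: int = 10_000
    generations: int = 100_000
    p_mut: float = 0.01
    mut_sd: float = 0.1
    replicates: int = 10
    record_fraction: float = 0.1
    seed: int = 0
    s_locked_at_zero: bool = False
    coordination_scope: str = "whole_group"
    cost_shape: str = "decelerating"
    init_q: float = 0.5
    init_s: float = 0.0
    resolution_passes: int = 1

    def __post_init__(self) -> None:
        if self.coordination_scope not in SCOPES:
            raise ValueError(f"coordination_scope must be one of {SCOPES}")
        if self.cost_shape not in COST_SHAPES:
            raise ValueError(f"cost_shape must be one of {COST_SHAPES}")
        for name in ("p_mut", "mut_sd", "record_fraction", "init_q", "init_s"):
            value = getattr(self, name)
            if name == "mut_sd":
                if value < 0:
                    raise ValueError("mut_sd must be >= 0")
            else:
                _check_proportion(name, value)
        if self.n_groups < 1:
            raise ValueError(
                f"target_pop_size {self.target_pop_size} is smaller than one "
                f"group of n = {self.params.n} cells"
            )
        if self.generations < 0 or self.replicates < 1 or self.resolution_passes < 1:
            raise ValueError("generations >= 0, replicates >= 1, passes >= 1 required")
        if self.s_locked_at_zero and self.init_s != 0.0:
            raise ValueError("s_locked_at_zero requires init_s = 0")

    @property
    def n_groups(self) -> int:
        return self.target_pop_size // self.params.n

    @property
    def pop_size(self) -> int:
        """Realized constant population size ``n_groups * l * m``."""
        return self.n_groups * self.params.n


def coordination_cost(
    s: float | np.ndarray, theta: float, shape: str = "decelerating"
) -> float | np.ndarray:
    """Fecundity cost of coordinating at level ``s``.

    All shapes share the endpoints cost(0) = 0 and cost(1) =
    theta*(1 - e^-5) so that only the curvature differs:

    - ``decelerating`` (default): theta*(1 - e^{-5s}), concave.
    - ``linear``: theta*s*(1 - e^-5).
    - ``accelerating``: theta*(1 - e^-5)*(e^{5s} - 1)/(e^5 - 1), convex.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("s must lie in [0, 1]")
    top = 1.0 - math.exp(-5.0)
    if shape == "decelerating":
        out = theta * (1.0 - np.exp(-5.0 * s))
    elif shape == "linear":
        out = theta * s * top
    elif shape == "accelerating":
        out = theta * top * (np.expm1(5.0 * s)) / math.expm1(5.0)
    else:
        raise ValueError(f"unknown cost shape {shape!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class GroupBatch:
    """All social groups of one generation, vectorized across groups.

    Arrays are indexed ``[group, cell]``; cells ``j*m .. (j+1)*m - 1``
    belong to lineage ``j``. ``links[g, i, j]`` is True when cell ``i``
    observes cell ``j`` (a one-way link; no self-links). A single group
    is simply the ``G = 1`` case.
    """

    params: ModelParams
    founder_q: np.ndarray  # (G, l)
    founder_s: np.ndarray  # (G, l)
    q: np.ndarray  # (G, n) per-cell target
    s: np.ndarray  # (G, n) per-cell coordination level
    lineage_of_cell: np.ndarray  # (n,)
    links: np.ndarray | None = None  # (G, n, n) bool
    intended_helper: np.ndarray | None = None  # (G, n) bool
    realized_helper: np.ndarray | None = None  # (G, n) bool

    @property
    def n_groups(self) -> int:
        return self.q.shape[0]

    @property
    def P(self) -> np.ndarray:
        """Realized helper proportion per group."""
        if self.realized_helper is None:
            raise RuntimeError("phenotypes not resolved yet")
        return self.realized_helper.mean(axis=1)


def grow_groups(
    founder_q: np.ndarray, founder_s: np.ndarray, params: ModelParams
) -> GroupBatch:
    """Grow each founder into a lineage of ``m`` clonal cells.

    ``founder_q`` and ``founder_s`` have shape ``(G, l)``; the resulting
    groups hold ``n = l*m`` cells each, every cell inheriting its
    founder's genotype.
    """
    founder_q = np.asarray(founder_q, dtype=float)
    founder_s = np.asarray(founder_s, dtype=float)
    if founder_q.ndim != 2 or founder_q.shape[1] != params.l:
        raise ValueError(
            f"founder arrays must have shape (G, l={params.l}), got {founder_q.shape}"
        )
    if founder_q.shape != founder_s.shape:
        raise ValueError("founder_q and founder_s shapes differ")
    q = np.repeat(founder_q, params.m, axis=1)
    s = np.repeat(founder_s, params.m, axis=1)
    lineage = np.repeat(np.arange(params.l), params.m)
    return GroupBatch(
        params=params,
        founder_q=founder_q,
        founder_s=founder_s,
        q=q,
        s=s,
        lineage_of_cell=lineage,
    )


def build_links(
    groups: GroupBatch, rng: np.random.Generator, scope: str = "whole_group"
) -> np.ndarray:
    """Draw the directed observation network of every group.

    Cell ``i`` observes cell ``j != i`` independently with probability
    ``s_i`` (the receiver's coordination level). Under ``own_lineage``
    scope links are restricted to clone-mates.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    G, n = groups.q.shape
    links = rng.random((G, n, n)) < groups.s[:, :, None]
    idx = np.arange(n)
    links[:, idx, idx] = False
    if scope == "own_lineage":
        same = groups.lineage_of_cell[:, None] == groups.lineage_of_cell[None, :]
        links &= same[None, :, :]
    groups.links = links
    return links


def resolve_phenotypes(
    groups: GroupBatch,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
    passes: int = 1,
) -> np.ndarray:
    """Sequentially settle each cell's helper/reproductive phenotype.

    All cells start as intended reproductives. Cells are visited exactly
    once per pass in a uniformly random order (one independent order per
    group); the visited cell becomes an intended helper iff the fraction
    of intended helpers among its observed senders, at visit time, is
    strictly below its target ``q``. A cell with no in-links randomizes:
    helper with probability ``q``. The final intended phenotypes are the
    realized phenotypes.

    ``order`` (shape ``(G, n)``, a permutation per row) overrides the
    random visit order; intended for tests.
    """
    if groups.links is None:
        raise RuntimeError("build_links must run before resolve_phenotypes")
    G, n = groups.q.shape
    intended = np.zeros((G, n), dtype=bool)
    gidx = np.arange(G)
    for _ in range(passes):
        if order is None:
            visit = np.argsort(rng.random((G, n)), axis=1)
        else:
            visit = np.asarray(order)
            if visit.shape != (G, n):
                raise ValueError(f"order must have shape {(G, n)}")
        u = rng.random((G, n))
        for t in range(n):
            i = visit[:, t]
            senders = groups.links[gidx, i, :]  # (G, n)
            indeg = senders.sum(axis=1)
            observed_helpers = (senders & intended).sum(axis=1)
            frac = observed_helpers / np.maximum(indeg, 1)
            qi = groups.q[gidx, i]
            coordinated = indeg > 0
            intended[gidx, i] = np.where(coordinated, frac < qi, u[gidx, i] < qi)
    groups.intended_helper = intended
    groups.realized_helper = intended.copy()
    return groups.realized_helper


def group_fecundities(
    groups: GroupBatch, params: ModelParams, cost_shape: str = "decelerating"
) -> np.ndarray:
    """Per-cell fecundity ``(1 - cost(s)) * (1 - h) * (1 - eps + eps*P)``.

    Helpers (h = 1) have fecundity 0; each reproductive pays its own
    coordination cost and benefits from the whole group's realized helper
    fraction ``P``.
    """
    if groups.realized_helper is None:
        raise RuntimeError("resolve_phenotypes must run before group_fecundities")
    P = groups.P[:, None]
    cost = coordination_cost(groups.s, params.theta, cost_shape)
    w = (1.0 - cost) * (~groups.realized_helper) * (1.0 - params.epsilon + params.epsilon * P)
    return w


def mutate(
    founder_q: np.ndarray,
    founder_s: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate founder traits in place-free fashion.

    Each trait of each founder mutates independently with probability
    ``p_mut``; a mutation adds a Normal(0, mut_sd) deviation and the
    result is clamped to [0, 1]. ``s`` never mutates when the control
    scenario locks it at zero.
    """
    q = np.array(founder_q, dtype=float, copy=True)
    s = np.array(founder_s, dtype=float, copy=True)
    mask_q = rng.random(q.shape) < config.p_mut
    q[mask_q] = np.clip(q[mask_q] + rng.normal(0.0, config.mut_sd, mask_q.sum()), 0, 1)
    mask_s = rng.random(s.shape) < config.p_mut
    if not config.s_locked_at_zero:
        s[mask_s] = np.clip(
            s[mask_s] + rng.normal(0.0, config.mut_sd, mask_s.sum()), 0, 1
        )
    return q, s


def next_generation(
    groups: GroupBatch,
    fecundity: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample next-generation founders by global competition.

    Founders are drawn multinomially from all cells of the population
    with probabilities proportional to fecundity (helpers weight 0;
    which group a parent sat in is irrelevant under global dispersal),
    inherit their parent's genotype, and then mutate.
    """
    G = groups.n_groups
    w = fecundity.ravel()
    total = w.sum()
    if total <= 0.0:
        raise RuntimeError(
            "total fecundity is zero (every cell became a helper); check "
            "epsilon/q initial conditions"
        )
    k = G * config.params.l
    counts = rng.multinomial(k, w / total)
    parents = np.repeat(np.arange(w.size), counts)
    # random assignment of sampled founders to groups/slots
    rng.shuffle(parents)
    fq = groups.q.ravel()[parents].reshape(G, config.params.l)
    fs = groups.s.ravel()[parents].reshape(G, config.params.l)
    return mutate(fq, fs, config, rng)


@dataclass(frozen=True)
class Trajectory:
    """Per-generation population means of one evolutionary run."""

    mean_q: np.ndarray
    mean_s: np.ndarray
    mean_P: np.ndarray
    config: SimConfig
    seed: int

    def __len__(self) -> int:
        return self.mean_q.size

    def window_means(self, fraction: float | None = None) -> dict[str, float]:
        """Time-averages over the trailing ``fraction`` of generations."""
        fraction = self.config.record_fraction if fraction is None else fraction
        k = max(1, int(round(fraction * len(self))))
        return {
            "mean_q": float(self.mean_q[-k:].mean()),
            "mean_s": float(self.mean_s[-k:].mean()),
            "mean_P": float(self.mean_P[-k:].mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self)),
                "mean_q": self.mean_q,
                "mean_s": self.mean_s,
                "mean_P": self.mean_P,
            }
        )


def _develop(
    founder_q: np.ndarray,
    founder_s: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GroupBatch, np.ndarray]:
    """Grow, link, resolve and score one generation's groups."""
    groups = grow_groups(founder_q, founder_s, config.params)
    G, n = groups.q.shape
    if np.all(groups.s == 0.0):
        # fully random fast path: no network, each cell flips its own coin
        groups.links = np.zeros((G, n, n), dtype=bool)
        groups.intended_helper = rng.random((G, n)) < groups.q
        groups.realized_helper = groups.intended_helper.copy()
    else:
        build_links(groups, rng, config.coordination_scope)
        resolve_phenotypes(groups, rng, passes=config.resolution_passes)
    w = group_fecundities(groups, config.params, config.cost_shape)
    return groups, w


def run_replicate(config: SimConfig, seed: int | None = None) -> Trajectory:
    """One full evolutionary run; bit-reproducible for a given seed.

    Records per-generation population means of the two traits (over
    cells, equal to founder means) and of the realized helper fraction.
    With ``generations = 0`` a single development pass of the initial
    population is recorded without any selection.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    G, l = config.n_groups, config.params.l
    fq = np.full((G, l), config.init_q, dtype=float)
    fs = np.full((G, l), config.init_s, dtype=float)
    steps = max(1, config.generations)
    mean_q = np.empty(steps)
    mean_s = np.empty(steps)
    mean_P = np.empty(steps)
    for g in range(steps):
        groups, w = _develop(fq, fs, config, rng)
        mean_q[g] = groups.q.mean()
        mean_s[g] = groups.s.mean()
        mean_P[g] = groups.P.mean()
        if config.generations > 0:
            fq, fs = next_generation(groups, w, config, rng)
    return Trajectory(mean_q, mean_s, mean_P, config, seed)


@dataclass(frozen=True)
class ExperimentResult:
    """Replicate-level trailing-window summaries plus across-replicate stats."""

    config: SimConfig
    per_replicate: pd.DataFrame  # columns: replicate, seed, mean_q, mean_s, mean_P
    trajectories: tuple[Trajectory, ...] = field(repr=False, default=())

    def summary(self) -> pd.DataFrame:
        """Across-replicate mean and standard error of each windowed mean."""
        rows = []
        r = len(self.per_replicate)
        for col in ("mean_q", "mean_s", "mean_P"):
            vals = self.per_replicate[col].to_numpy()
            se = vals.std(ddof=1) / math.sqrt(r) if r > 1 else 0.0
            rows.append({"quantity": col, "mean": vals.mean(), "se": se, "n": r})
        return pd.DataFrame(rows)


def replicate_seeds(master_seed: int, replicates: int) -> list[int]:
    """Independent per-replicate seeds derived from the master seed.

    Uses SeedSequence spawning so that increasing the replicate count
    never changes the streams of earlier replicates.
    """
    children = np.random.SeedSequence(master_seed).spawn(replicates)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_experiment(
    config: SimConfig, keep_trajectories: bool = True
) -> ExperimentResult:
    """Run ``config.replicates`` independent replicates and summarize.

    Each replicate gets its own deterministic seed derived from
    ``config.seed``; summaries are time-averages over the trailing
    ``record_fraction`` of generations.
    """
    seeds = replicate_seeds(config.seed, config.replicates)
    rows = []
    trajectories = []
    for i, s in enumerate(seeds):
        traj = run_replicate(config, seed=s)
        if keep_trajectories:
            trajectories.append(traj)
        rows.append({"replicate": i, "seed": s, **traj.window_means()})
    return ExperimentResult(
        config=config,
        per_replicate=pd.DataFrame(rows),
        trajectories=tuple(trajectories),
    )


@dataclass(frozen=True)
class VarianceRatioReport:
    """Across-replicate variance comparison of coordination vs helping."""

    var_s: float
    var_P: float
    ratio: float  # var_s / var_P
    f_statistic: float
    p_value: float
    df: tuple[int, int]
    degenerate: bool


def variability_test(
    trajectories: Sequence[Trajectory], window: float | None = None
) -> VarianceRatioReport:
    """F-test comparing across-replicate variance of evolved s vs P.

    Computes each replicate's trailing-window means of the coordination
    level and of the helper proportion, then the ratio of their
    across-replicate variances with a two-sided variance-ratio (F)
    p-value. A zero variance in the denominator is reported as
    degenerate rather than raised. Reports only; asserts nothing.
    """
    if len(trajectories) < 2:
        raise ValueError("variability_test needs at least two replicates")
    s_bar = np.array([t.window_means(window)["mean_s"] for t in trajectories])
    P_bar = np.array([t.window_means(window)["mean_P"] for t in trajectories])
    var_s = float(s_bar.var(ddof=1))
    var_P = float(P_bar.var(ddof=1))
    df = (len(trajectories) - 1, len(trajectories) - 1)
    if var_P == 0.0 or var_s == 0.0:
        return VarianceRatioReport(
            var_s, var_P, math.nan, math.nan, math.nan, df, True
        )
    f_stat = var_s / var_P
    cdf = stats.f.cdf(f_stat, *df)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return VarianceRatioReport(var_s, var_P, f_stat, f_stat, min(p, 1.0), df, False)
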