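"""Analytical game theory of random vs coordinated division of labor.

Two extreme mechanisms are compared. A *fully random* specializer
lineage lets each cell become a sterile helper independently with
probability ``q`` (its heritable target helper proportion), so the
realized helper fraction fluctuates binomially around the target. A
*fully coordinated* lineage uses within-lineage signalling to hit the
target exactly, at a flat fecundity cost ``theta``.

The expected fitness of a focal founder with target ``q`` in a group
whose other founders use target ``Q`` is

    w_random(q, Q)      = (1-q) * (1-eps + eps*q/l + eps*(l-1)*Q/l - eps*q/(l*m))
    w_coordinated(q, Q) = (1-theta) * (1-q) * (1-eps + eps*q/l + eps*(l-1)*Q/l)

The final ``eps*q/(l*m)`` term in the random case is the fecundity cost
of stochastic deviations from the target; it is exactly the covariance
between a lineage's reproductive fraction and the group helper fraction
under binomial sampling (see :func:`fitness_random_exact`).

Both fitness functions are concave quadratics in ``q``, so each
mechanism has a unique symmetric ESS target proportion:

    q_random*      = 0 if eps <= l*m/(l*m + m - 1)
                     else (m - 1 - l*m*(1-eps)/eps) / (l*m + m - 2)
    q_coordinated* = 0 if eps <= l/(l+1)
                     else (1 - l*(1-eps)/eps) / (l + 1)

These closed forms are validated in the test suite against a numeric
best-response fixed point; :func:`ess_numeric` remains available as the
independent route.

Pairwise invasion between the mechanisms at their resident ESS reduces
to closed conditions on the product ``theta*l*m``:

    random invades coordinated  <=>  eps <= theta*l*m / (theta*l*m*(1-q_c*) + q_c*)
    coordinated invades random  <=>  eps >  theta*l*m / (theta*l*m*(1-q_r*) + q_r*)

Fitness ties are resolved in favor of the random specializer — the
mechanism that builds no coordination machinery — so ``theta*l*m >= 1``
makes random specialization invade everywhere and remain uninvadable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

from .params import ModelParams, _check_proportion

__all__ = [
    "Mechanism",
    "Region",
    "ESSResult",
    "InvasionReport",
    "PhaseGrid",
    "fitness_random",
    "fitness_random_exact",
    "fitness_coordinated",
    "best_response",
    "ess_numeric",
    "ess_random_closed",
    "ess_coordinated_closed",
    "random_invades_coordinated",
    "coordinated_invades_random",
    "classify_region",
    "phase_grid",
]

#: two fitness evaluations closer than this are a neutral tie
_TIE_TOL = 1e-12


class Mechanism(str, enum.Enum):
    RANDOM = "random"
    COORDINATED = "coordinated"


class Region(str, enum.Enum):
    NO_DIVISION_OF_LABOR = "no_division_of_labor"
    RANDOM_WINS = "random_wins"
    COORDINATED_WINS = "coordinated_wins"
    NEITHER_INVADES = "neither_invades"
    MUTUAL_INVASION = "mutual_invasion"


class InvasionMode(str, enum.Enum):
    """How the invading mutant chooses its target helper proportion.

    ``RESIDENT_Q``: the mutant copies the resident's ESS target, so only
    the mechanism differs. ``MUTANT_OPTIMAL_Q``: the mutant plays its own
    mechanism's best response to the resident ESS; this mode can produce
    mutual invadability.
    """

    RESIDENT_Q = "resident_q"
    MUTANT_OPTIMAL_Q = "mutant_optimal_q"


@dataclass(frozen=True)
class ESSResult:
    mechanism: Mechanism
    q_star: float
    interior: bool
    method: str  # "closed_form" | "numeric_best_response"


@dataclass(frozen=True)
class InvasionReport:
    random_invades_coordinated: bool
    coordinated_invades_random: bool
    region: Region
    q_res_random: float
    q_res_coordinated: float
    mode: InvasionMode


@dataclass(frozen=True)
class PhaseGrid:
    """Invasion outcomes over an (epsilon, n) grid at fixed l, theta.

    ``table`` is tidy: one row per grid cell with columns
    ``l, m, n, epsilon, theta, mode, q_fr, q_fc, region, valid``.
    Cells whose ``n`` is not divisible by ``l`` are kept but flagged
    ``valid=False`` with no results, never silently rounded.
    """

    l: int
    theta: float
    axis_epsilon: np.ndarray
    axis_n: np.ndarray
    mode: InvasionMode
    table: pd.DataFrame

    def region_counts(self) -> pd.Series:
        return self.table.loc[self.table["valid"], "region"].value_counts()


# ---------------------------------------------------------------------------
# fitness functions


def fitness_random(q: float, Q: float, params: ModelParams) -> float:
    """Expected fitness of a random-specializer founder.

    ``q`` is the focal founder's target helper proportion, ``Q`` the
    target of the other ``l - 1`` founders in the group.
    """
    q = _check_proportion("q", q)
    Q = _check_proportion("Q", Q)
    l, m, eps = params.l, params.m, params.epsilon
    return (1.0 - q) * (
        1.0 - eps + eps * q / l + eps * (l - 1) * Q / l - eps * q / (l * m)
    )


def fitness_random_exact(q: float, Q: float, params: ModelParams) -> float:
    """Binomial-expectation oracle for :func:`fitness_random`.

    Enumerates the focal lineage's helper count k ~ Binomial(m, q) and
    averages ``(1 - k/m) * (1 - eps + eps * P)`` with the other lineages
    entering at their expected helper count (valid because fecundity is
    linear in their contribution to ``P``). Agrees with the closed form
    to floating-point precision; kept as an independent check, not a
    fast path.
    """
    q = _check_proportion("q", q)
    Q = _check_proportion("Q", Q)
    l, m, eps = params.l, params.m, params.epsilon
    k = np.arange(m + 1)
    pmf = binom.pmf(k, m, q)
    fecundity = 1.0 - eps + eps * (k + (l - 1) * Q * m) / (l * m)
    return float(np.sum(pmf * (1.0 - k / m) * fecundity))


def fitness_coordinated(q: float, Q: float, params: ModelParams) -> float:
    """Expected fitness of a fully coordinated founder (exact ``q`` helpers)."""
    q = _check_proportion("q", q)
    Q = _check_proportion("Q", Q)
    l, eps, theta = params.l, params.epsilon, params.theta
    if theta > 1.0:
        raise ValueError(f"theta must lie in [0, 1] for a fecundity cost, got {theta}")
    return (1.0 - theta) * (1.0 - q) * (1.0 - eps + eps * q / l + eps * (l - 1) * Q / l)


def _quadratic_coeffs(mechanism: Mechanism, params: ModelParams) -> tuple[float, float]:
    """Return (A, B): within-lineage and cross-lineage fecundity slopes.

    Both fitness functions have the shape ``scale * (1-q)(1-eps + A*q + B*Q)``
    with A > 0 unless degenerate; A differs between mechanisms by the
    stochasticity penalty eps/(l*m).
    """
    l, m, eps = params.l, params.m, params.epsilon
    B = eps * (l - 1) / l
    if mechanism == Mechanism.RANDOM:
        A = eps * (m - 1) / (l * m)
    else:
        A = eps / l
    return A, B


def best_response(mechanism: Mechanism, Q: float, params: ModelParams) -> float:
    """Fitness-maximizing target ``q`` against a resident target ``Q``.

    The fitness is a concave quadratic in ``q`` (the ``1-theta`` scale of
    the coordinated mechanism does not move the argmax), so the maximizer
    is the vertex clipped to [0, 1].
    """
    Q = _check_proportion("Q", Q)
    mechanism = Mechanism(mechanism)
    A, B = _quadratic_coeffs(mechanism, params)
    C = 1.0 - params.epsilon + B * Q
    if A <= 0.0:
        # fitness (1-q)*C is nonincreasing in q
        return 0.0
    return float(min(max((A - C) / (2.0 * A), 0.0), 1.0))


# ---------------------------------------------------------------------------
# ESS target helper proportions


def ess_numeric(mechanism: Mechanism, params: ModelParams) -> ESSResult:
    """Symmetric ESS as the fixed point of the best response.

    ``g(q) = best_response(q) - q`` is continuous and strictly decreasing
    (the best response is linear in the resident target with negative
    slope before clipping), so the fixed point is unique: ``q* = 0`` when
    ``g(0) <= 0``, otherwise the bracketed root of ``g``.
    """
    mechanism = Mechanism(mechanism)
    A, _ = _quadratic_coeffs(mechanism, params)
    if A < 0:  # concavity guard; cannot occur for valid params
        raise RuntimeError("fitness is not concave in q; ESS undefined")

    def g(q: float) -> float:
        return best_response(mechanism, q, params) - q

    if g(0.0) <= 0.0:
        q_star = 0.0
    else:
        # g(1) = BR(1) - 1 < 0 because BR < 1 whenever baseline fecundity
        # or cross-lineage help is positive; brentq converges on [0, 1].
        q_star = brentq(g, 0.0, 1.0, xtol=1e-12)
        if abs(g(q_star)) > 1e-10:
            raise RuntimeError("best-response fixed point did not converge")
    return ESSResult(mechanism, float(q_star), q_star > 0.0, "numeric_best_response")


def ess_random_closed(params: ModelParams) -> ESSResult:
    """Closed-form ESS target proportion for random specializers."""
    l, m, eps = params.l, params.m, params.epsilon
    denom = l * m + m - 2
    if denom == 0:  # (l, m) = (1, 1): a lone cell that helps has fitness 0
        return ESSResult(Mechanism.RANDOM, 0.0, False, "closed_form")
    threshold = l * m / (l * m + m - 1)
    if eps <= threshold:
        return ESSResult(Mechanism.RANDOM, 0.0, False, "closed_form")
    q_star = (eps * (m - 1) - l * m * (1.0 - eps)) / (eps * denom)
    q_star = float(min(max(q_star, 0.0), 1.0))
    return ESSResult(Mechanism.RANDOM, q_star, q_star > 0.0, "closed_form")


def ess_coordinated_closed(params: ModelParams) -> ESSResult:
    """Closed-form ESS target proportion for coordinated specializers.

    Independent of lineage size ``m`` (no stochasticity penalty) and of
    the cost ``theta`` (a flat factor does not move the optimum).
    """
    l, eps = params.l, params.epsilon
    threshold = l / (l + 1)
    if eps <= threshold:
        return ESSResult(Mechanism.COORDINATED, 0.0, False, "closed_form")
    q_star = (eps - l * (1.0 - eps)) / (eps * (l + 1))
    q_star = float(min(max(q_star, 0.0), 1.0))
    return ESSResult(Mechanism.COORDINATED, q_star, q_star > 0.0, "closed_form")


def ess(mechanism: Mechanism, params: ModelParams) -> ESSResult:
    """Closed-form ESS for either mechanism."""
    mechanism = Mechanism(mechanism)
    if mechanism == Mechanism.RANDOM:
        return ess_random_closed(params)
    return ess_coordinated_closed(params)


# ---------------------------------------------------------------------------
# pairwise invasion analysis


def _invasion_margin(q_res: float, params: ModelParams) -> float:
    """w_random - w_coordinated for a monomorphic resident target ``q_res``."""
    return fitness_random(q_res, q_res, params) - fitness_coordinated(
        q_res, q_res, params
    )


def _closed_threshold(q_res: float, params: ModelParams) -> float | None:
    """The epsilon threshold theta*l*m / (theta*l*m*(1-q) + q), or None if 0/0."""
    tlm = params.theta * params.l * params.m
    denom = tlm * (1.0 - q_res) + q_res
    if denom == 0.0:
        return None
    return tlm / denom


def random_invades_coordinated(params: ModelParams, q_res: float) -> bool:
    """Can a rare random specializer invade coordinated residents at ESS ``q_res``?

    Evaluates both the closed threshold condition on epsilon and the
    direct fitness comparison ``w_random >= w_coordinated`` at the
    resident target; the two routes must agree (ties go to the random
    mechanism). A disagreement beyond tolerance raises, since both are
    algebraic rearrangements of the same inequality.
    """
    q_res = _check_proportion("q_res", q_res)
    margin = _invasion_margin(q_res, params)
    direct = margin >= -_TIE_TOL
    thr = _closed_threshold(q_res, params)
    if thr is not None:
        closed = params.epsilon <= thr + _TIE_TOL
        if closed != direct and abs(margin) > _TIE_TOL:
            raise RuntimeError(
                "closed invasion condition disagrees with direct fitness "
                f"comparison (margin={margin:.3e})"
            )
    return direct


def coordinated_invades_random(params: ModelParams, q_res: float) -> bool:
    """Can a rare coordinated specializer invade random residents at ESS ``q_res``?

    Strict advantage is required (a neutral coordinator does not invade);
    a resident with no helpers (``q_res = 0``) offers nothing for
    coordination to improve on and is never invaded.
    """
    q_res = _check_proportion("q_res", q_res)
    if q_res == 0.0:
        return False
    margin = _invasion_margin(q_res, params)
    direct = margin < -_TIE_TOL
    thr = _closed_threshold(q_res, params)
    if thr is not None:
        closed = params.epsilon > thr + _TIE_TOL
        if closed != direct and abs(margin) > _TIE_TOL:
            raise RuntimeError(
                "closed invasion condition disagrees with direct fitness "
                f"comparison (margin={margin:.3e})"
            )
    return direct


def classify_region(
    params: ModelParams, mode: InvasionMode | str = InvasionMode.RESIDENT_Q
) -> InvasionReport:
    """Pairwise invasion outcome between the two mechanisms.

    In ``resident_q`` mode each mutant copies the resident's ESS target;
    in ``mutant_optimal_q`` mode each mutant plays its own best response
    to the resident ESS (which can make the mechanisms mutually
    invadable). When neither mechanism sustains helpers at ESS the cell
    is ``no_division_of_labor`` and no invasion is evaluated.
    """
    mode = InvasionMode(mode)
    q_fr = ess_random_closed(params).q_star
    q_fc = ess_coordinated_closed(params).q_star
    if q_fr == 0.0 and q_fc == 0.0:
        return InvasionReport(
            False, False, Region.NO_DIVISION_OF_LABOR, q_fr, q_fc, mode
        )
    if mode == InvasionMode.RESIDENT_Q:
        rand_inv = random_invades_coordinated(params, q_fc)
        coord_inv = coordinated_invades_random(params, q_fr)
    else:
        q_mut_r = best_response(Mechanism.RANDOM, q_fc, params)
        rand_inv = (
            fitness_random(q_mut_r, q_fc, params)
            - fitness_coordinated(q_fc, q_fc, params)
            >= -_TIE_TOL
        )
        if q_fr == 0.0:
            coord_inv = False
        else:
            q_mut_c = best_response(Mechanism.COORDINATED, q_fr, params)
            coord_inv = (
                fitness_coordinated(q_mut_c, q_fr, params)
                - fitness_random(q_fr, q_fr, params)
                > _TIE_TOL
            )
    if rand_inv and coord_inv:
        region = Region.MUTUAL_INVASION
    elif rand_inv:
        region = Region.RANDOM_WINS
    elif coord_inv:
        region = Region.COORDINATED_WINS
    else:
        region = Region.NEITHER_INVADES
    return InvasionReport(rand_inv, coord_inv, region, q_fr, q_fc, mode)


def phase_grid(
    l: int,
    theta: float,
    epsilon_axis: Sequence[float],
    n_axis: Sequence[int],
    mode: InvasionMode | str = InvasionMode.RESIDENT_Q,
) -> PhaseGrid:
    """Invasion outcomes over an essentiality x group-size grid at fixed l.

    Group sizes not divisible by ``l`` cannot be realized by ``l`` equal
    lineages; such cells are flagged invalid rather than rounded.
    """
    epsilon_axis = np.asarray(list(epsilon_axis), dtype=float)
    n_axis = np.asarray(list(n_axis), dtype=int)
    if epsilon_axis.size == 0 or n_axis.size == 0:
        raise ValueError("phase_grid axes must be non-empty")
    mode = InvasionMode(mode)
    rows = []
    for n in n_axis:
        divisible = n % l == 0
        for eps in epsilon_axis:
            row = {
                "l": l,
                "m": n // l if divisible else np.nan,
                "n": int(n),
                "epsilon": float(eps),
                "theta": float(theta),
                "mode": mode.value,
                "q_fr": np.nan,
                "q_fc": np.nan,
                "region": "",
                "valid": bool(divisible),
            }
            if divisible:
                params = ModelParams(l=l, m=int(n // l), epsilon=float(eps), theta=theta)
                report = classify_region(params, mode)
                row["q_fr"] = report.q_res_random
                row["q_fc"] = report.q_res_coordinated
                row["region"] = report.region.value
            rows.append(row)
    table = pd.DataFrame(rows)
    return PhaseGrid(
        l=int(l),
        theta=float(theta),
        axis_epsilon=epsilon_axis,
        axis_n=n_axis,
        mode=mode,
        table=table,
    )
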