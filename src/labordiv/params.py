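"""Shared parameters of the social-group life cycle.

Groups follow a haystack life cycle: ``l`` founding cells each spawn a
lineage of ``m`` cells, the mature group of ``n = l*m`` cells divides
labor into sterile helpers and pure reproductives, reproductives seed a
global offspring pool, and the pool founds the next round of groups.
Whole-group relatedness (probability that two group members, sampling
with replacement, descend from the same founder) is ``1/l``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the division-of-labor game.

    Parameters
    ----------
    l : int
        Number of founding lineages per group (>= 1). Sets whole-group
        relatedness ``1/l``; ``l = 1`` is a clonal group.
    m : int
        Cells per lineage at maturity (>= 1).
    epsilon : float
        Essentiality of cooperation in [0, 1]. Reproductive fecundity is
        ``1 - epsilon + epsilon * P`` where ``P`` is the realized helper
        fraction of the group; ``epsilon = 1`` means no reproduction
        without helpers.
    theta : float
        Coordination cost coefficient (>= 0). Fully coordinated
        specializers pay a flat fecundity factor ``1 - theta``; in the
        individual-based model the cost scales with the coordination
        level ``s``.
    """

    l: int
    m: int
    epsilon: float
    theta: float = 0.025

    def __post_init__(self) -> None:
        if int(self.l) != self.l or self.l < 1:
            raise ValueError(f"l must be an integer >= 1, got {self.l}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.theta < 0.0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        object.__setattr__(self, "l", int(self.l))
        object.__setattr__(self, "m", int(self.m))

    @property
    def n(self) -> int:
        """Mature group size ``l * m``."""
        return self.l * self.m

    @property
    def relatedness(self) -> float:
        """Whole-group relatedness ``1/l`` (including self)."""
        return 1.0 / self.l


def _check_proportion(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value
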