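"""Stochastic primitives of the model.

All first-order events (decay, replication, dissociation) are memoryless:
the time to the event is drawn once, when the molecule or complex is
created, from an exponential distribution via inverse-transform sampling,
and then simply counted down in discrete steps.  Brownian motion is the
Euler-Maruyama update ``x += sqrt(2 D dt) * xi`` with independent standard
normal components.  Mutation perturbs an attribute additively by a bounded
uniform offset, clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import world as _world


@dataclass
class KineticParams:
    """Rate constants of the reaction-diffusion system.

    Defaults are the published constant set: decay ``d = 0.182`` per time
    unit, free-molecule diffusion ``D = 0.75``, complex diffusion
    ``D' = 0.0476`` (both length^2/time), replication rate ``K = 239800``
    (so large that the replication clock expires at its first decrement,
    realising a near-deterministic replication time), step length
    ``dt = 1`` and agent radius ``r = 0.5`` (collision distance 1, one
    lattice cell side).  ``n_max`` is the crowding cap: an entity seeing
    more than ``n_max`` neighbors is removed for lack of resources; 8 is
    the Moore-neighborhood capacity of the source lattice model.
    """

    d: float = 0.182
    D: float = 0.75
    D_complex: float = 0.0476
    K: float = 239800.0
    dt: float = 1.0
    radius: float = 0.5
    n_max: int = 8

    def __post_init__(self):
        for name in ("d", "D", "D_complex", "K"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be a positive integer")


@dataclass
class MutationParams:
    """Per-replication mutation model.

    Each offspring attribute (a, then l) is independently perturbed with
    probability ``mu_a`` / ``mu_l`` by a uniform offset on
    [-delta, +delta], clamped to [0, 1].  The per-species flags gate
    whether the corresponding attribute of that species can mutate at all
    (an unset flag is equivalent to a zero mutation probability for that
    species/attribute).
    """

    mu_a: float = 0.0
    mu_l: float = 0.0
    delta: float = 0.05
    mutate_a_replicase: bool = False
    mutate_l_replicase: bool = False
    mutate_a_parasite: bool = False
    mutate_l_parasite: bool = False

    def __post_init__(self):
        if not (0.0 <= self.mu_a <= 1.0 and 0.0 <= self.mu_l <= 1.0):
            raise ValueError("mutation probabilities must lie in [0, 1]")
        if self.delta <= 0:
            raise ValueError("mutation half-width delta must be positive")

    def effective_mu(self, species: str, attribute: str) -> float:
        """Mutation probability actually applied to one species/attribute."""
        flag = {
            ("replicase", "a"): self.mutate_a_replicase,
            ("replicase", "l"): self.mutate_l_replicase,
            ("parasite", "a"): self.mutate_a_parasite,
            ("parasite", "l"): self.mutate_l_parasite,
        }[(species, attribute)]
        mu = self.mu_a if attribute == "a" else self.mu_l
        return mu if flag else 0.0


def sample_waiting_time(k: float, u: float) -> float:
    """Inverse-transform exponential waiting time ``-ln(u)/k``.

    ``u`` must come from a draw on the half-open interval (0, 1]; u = 0 is
    rejected rather than clamped, because it signals a broken draw
    contract upstream.
    """
    if k <= 0:
        raise ValueError("rate k must be positive")
    if not (0.0 < u <= 1.0):
        raise ValueError("u must lie in (0, 1]")
    return -math.log(u) / k


def diffusion_step(p, coef: float, dt: float, gauss, geom: _world.TorusGeometry):
    """One Brownian displacement: each coordinate moves by
    sqrt(2 * coef * dt) times its standard-normal component, then wraps."""
    if coef < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = np.asarray(p, dtype=float)
    gauss = np.asarray(gauss, dtype=float)
    return _world.wrap_position(p + math.sqrt(2.0 * coef * dt) * gauss, geom)


def collision_distance(r_i: float, r_j: float) -> float:
    """Center-to-center distance below which two circular agents overlap."""
    if r_i <= 0 or r_j <= 0:
        raise ValueError("agent radii must be positive")
    return r_i + r_j


def reaction_probability(a_template: float, l_template: float) -> float:
    """Probability ``omega = a * (1 - l)`` that a collision forms a complex.

    Depends only on the *template's* affinity and folded-state probability;
    the catalyst's attributes never enter.
    """
    if not (0.0 <= a_template <= 1.0 and 0.0 <= l_template <= 1.0):
        raise ValueError("template attributes must lie in [0, 1]")
    return a_template * (1.0 - l_template)


def mutate_attribute(v: float, mu: float, delta: float, rng) -> float:
    """With probability ``mu``, perturb ``v`` by U(-delta, +delta), clamped
    to [0, 1]; otherwise return ``v`` unchanged.

    ``rng`` is a one-element uint64 generator state (see ``rpsim._rng``);
    exactly one uniform is consumed for the decision and, only if it
    fires, one more for the offset.
    """
    from . import _rng

    if not (0.0 <= v <= 1.0 and 0.0 <= mu <= 1.0):
        raise ValueError("v and mu must lie in [0, 1]")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if _rng.uniform(rng) >= mu:
        return v
    off = (2.0 * _rng.uniform(rng) - 1.0) * delta
    return min(1.0, max(0.0, v + off))
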