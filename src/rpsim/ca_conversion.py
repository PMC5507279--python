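"""Lattice-to-continuum parameter conversion.

The simulator inherits its rate constants from a cellular-automaton (CA)
ancestor in which molecules hop on a square lattice with a Moore (8-cell)
neighborhood.  Diffusion transfers analytically by matching the per-step
displacement variance of the lattice walk to that of the Brownian update
``sigma^2 = 2 D dt``.  The per-move variance enumerations are exposed so
the matching identities can be checked directly.

A free CA molecule's only possible action is a hop, so its hop probability
is 1; four of the eight Moore targets are at squared distance 1 and four
at squared distance 2, giving a per-step variance of ``(3/2) p``.  A
complexed CA molecule hops with half probability, in competition with
replication, so its hop probability is ``(d/2) / (d/2 + k)``; the
center-of-mass enumeration of a two-cell complex hop (four moves of
sqrt(2)/2, one of 1, two of sqrt(10)/2, one null), doubled because either
member can initiate, evaluates to exactly ``2 p'``.

The replication rate K is deliberately *not* converted: it is set so large
that the replication waiting time is effectively a Dirac delta at zero,
and the published value is carried as a scenario constant.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CAParams:
    """Source-lattice parameters: hop probability of a free molecule,
    diffusion and replication rates, and the target step length dt."""

    p_d_ca: float = 1.0
    d_ca: float = 0.1
    k_ca: float = 1.0
    dt: float = 1.0


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")


def single_move_variance_ca(p_d_ca: float) -> float:
    """Per-step displacement variance of a free lattice molecule:
    (1/8) * (4*1^2 + 4*(sqrt 2)^2) * p = (3/2) p."""
    _check_prob(p_d_ca, "p_d_ca")
    return 1.5 * p_d_ca


def mas_diffusion_from_ca(p_d_ca: float, dt: float) -> float:
    """Free-molecule diffusion coefficient D = 3 p / (4 dt), the unique
    value satisfying the variance match 2 D dt = (3/2) p."""
    _check_prob(p_d_ca, "p_d_ca")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return 3.0 * p_d_ca / (4.0 * dt)


def complex_move_probability_ca(d_ca: float, k_ca: float) -> float:
    """Hop probability of a complexed lattice molecule,
    p' = (d/2) / (d/2 + k): it hops at half the free rate, in competition
    with replication."""
    if d_ca < 0 or k_ca < 0:
        raise ValueError("rates must be non-negative")
    if d_ca == 0 and k_ca == 0:
        raise ValueError("p' is undefined when both rates are zero")
    return (d_ca / 2.0) / (d_ca / 2.0 + k_ca)


def complex_move_variance_ca(p_prime: float) -> float:
    """Per-step center-of-mass displacement variance of a lattice complex:
    (1/8) * (4*(sqrt2/2)^2 + 1 + 2*(sqrt10/2)^2) * 2 p' = 2 p'."""
    _check_prob(p_prime, "p_prime")
    return 2.0 * p_prime


def mas_complex_diffusion_from_ca(p_prime: float, dt: float) -> float:
    """Complex diffusion coefficient D' = p'/dt, the unique value
    satisfying the variance match 2 D' dt = 2 p'."""
    _check_prob(p_prime, "p_prime")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return p_prime / dt


def convert(params: CAParams) -> dict[str, float]:
    """Full conversion: returns D and D' for a CA parameter set."""
    p_prime = complex_move_probability_ca(params.d_ca, params.k_ca)
    return {
        "D": mas_diffusion_from_ca(params.p_d_ca, params.dt),
        "p_prime": p_prime,
        "D_complex": mas_complex_diffusion_from_ca(p_prime, params.dt),
    }
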