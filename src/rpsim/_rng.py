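"""Deterministic pseudo-random stream shared by all stochastic components.

A single xorshift64* generator drives every random decision in a run:
initial placement, lifetime draws, processing-order shuffles, Brownian
displacements, reaction tests and mutation offsets all consume from one
stream in a documented order, so a (seed, config) pair fully determines a
run.  The generator is implemented as a set of ``numba.njit`` routines
operating on a one-element ``uint64`` state array; the identical compiled
code is callable both from Python helpers and from inside the world-update
kernel, which is what makes the two entry points bit-compatible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MASK64 = (1 << 64) - 1
_STAR_MULT = np.uint64(0x2545F4914F6CDD1D)
# 2**-53: converts the top 53 bits of a draw to a double in [0, 1)
_TWO53_INV = 1.0 / 9007199254740992.0


def make_state(seed: int) -> np.ndarray:
    """Build a generator state from a non-negative integer seed.

    The seed is passed through one round of splitmix64 so that small,
    adjacent seeds yield well-separated states; the all-zero state (a
    fixed point of xorshift) is mapped to a fixed non-zero constant.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    z = (int(seed) + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z = z ^ (z >> 31)
    if z == 0:
        z = 0x9E3779B97F4A7C15
    return np.array([z], dtype=np.uint64)


@njit(cache=True)
def next_u64(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * _STAR_MULT


@njit(cache=True)
def uniform(state):
    """One double uniform on [0, 1)."""
    return (next_u64(state) >> np.uint64(11)) * _TWO53_INV


@njit(cache=True)
def open_uniform(state):
    """One double uniform on (0, 1] — the draw contract for waiting times."""
    return 1.0 - uniform(state)


@njit(cache=True)
def normal_pair(state):
    """Two independent standard normals via the Box-Muller transform."""
    u1 = open_uniform(state)
    u2 = uniform(state)
    r = math.sqrt(-2.0 * math.log(u1))
    t = 2.0 * math.pi * u2
    return r * math.cos(t), r * math.sin(t)


@njit(cache=True)
def randint(state, n):
    """One integer uniform on {0, ..., n-1} (n <= 2**32; modulo bias < 2**-31)."""
    return int(next_u64(state) % np.uint64(n))


@njit(cache=True)
def shuffle(buf, n, state):
    """In-place Fisher-Yates shuffle of buf[:n]."""
    for k in range(n - 1, 0, -1):
        j = randint(state, k + 1)
        tmp = buf[k]
        buf[k] = buf[j]
        buf[j] = tmp
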