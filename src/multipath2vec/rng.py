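"""Deterministic PCG32 random generator.

The walk generator and the skip-gram trainer each exist in two forms: a
pure-Python reference implementation and a numba-jitted fast path. Both
forms of a component must consume *identical* random streams so they can be
cross-checked for equality, which rules out numpy's ``Generator`` (not
callable from inside an njit kernel with shared state). PCG32 (O'Neill's
``pcg32_random_r``) is small enough to implement twice, once here in pure
Python and once as njit helpers operating on a 2-element uint64 state array.

Distinct logical streams (walks, parameter init, training) are separated via
the PCG32 stream-selector constant so one user-facing seed drives them all
without overlap.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_MASK64 = (1 << 64) - 1
_MASK32 = (1 << 32) - 1
_PCG_MULT = 6364136223846793005

# stream selectors: one per logical purpose, so a single user seed never
# produces overlapping draw sequences across pipeline stages
STREAM_WALK = 1
STREAM_INIT = 2
STREAM_TRAIN = 3
STREAM_DEFAULT = 0


class PCG32:
    """Pure-Python PCG32 (XSH-RR 64/32)."""

    def __init__(self, seed: int, stream: int = STREAM_DEFAULT) -> None:
        self.state = 0
        self.inc = ((stream << 1) | 1) & _MASK64
        self._advance()
        self.state = (self.state + (seed & _MASK64)) & _MASK64
        self._advance()

    def _advance(self) -> None:
        self.state = (self.state * _PCG_MULT + self.inc) & _MASK64

    def next_uint32(self) -> int:
        old = self.state
        self._advance()
        xorshifted = (((old >> 18) ^ old) >> 27) & _MASK32
        rot = old >> 59
        return ((xorshifted >> rot) | (xorshifted << ((32 - rot) & 31))) & _MASK32

    def random(self) -> float:
        """Uniform double in [0, 1)."""
        return self.next_uint32() / 4294967296.0

    def state_array(self) -> np.ndarray:
        """Export state for the njit twin: [state, inc] as uint64."""
        return np.array([self.state, self.inc], dtype=np.uint64)

    def set_state_array(self, arr: np.ndarray) -> None:
        self.state = int(arr[0])
        self.inc = int(arr[1])


def pcg32_state(seed: int, stream: int = STREAM_DEFAULT) -> np.ndarray:
    """State array for the njit functions, seeded like :class:`PCG32`."""
    return PCG32(seed, stream).state_array()


@njit(cache=True)
def pcg32_next_uint32(state: np.ndarray) -> np.uint32:
    old = state[0]
    state[0] = old * np.uint64(6364136223846793005) + state[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32(
        (xorshifted >> rot) | (xorshifted << (np.uint32(32 - rot) & np.uint32(31)))
    )


@njit(cache=True)
def pcg32_random(state: np.ndarray) -> float:
    return pcg32_next_uint32(state) / 4294967296.0
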