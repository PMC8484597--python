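"""Counter-seeded pseudo-random number generation.

The transport kernel needs a uniform generator that (a) runs inside
compiled numba code, (b) gives every photon its own deterministic
substream keyed by (seed, photon index) so ensemble results do not
depend on batching, and (c) can be wrapped by a precision-quantization
layer that emulates reduced-precision generators.  xoshiro256++ with
splitmix64 state initialization satisfies all three; uniforms carry the
full 53-bit double-precision mantissa.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RandomStream", "init_state", "next_uniform"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + _GOLDEN) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _MIX1) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _MIX2) & _U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _rotl(x, k):
    return ((x << k) | (x >> (_U64(64) - k))) & _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def init_state(state, seed, stream_index):
    """Fill the 4-word xoshiro256++ state for substream `stream_index`."""
    z = (_U64(seed) ^ (_U64(stream_index) * _GOLDEN)) & _U64(0xFFFFFFFFFFFFFFFF)
    z1 = _splitmix64(z)
    z2 = _splitmix64(z1)
    z3 = _splitmix64(z2)
    z4 = _splitmix64(z3)
    state[0] = z1
    state[1] = z2
    state[2] = z3
    state[3] = z4
    if state[0] == _U64(0) and state[1] == _U64(0) and state[2] == _U64(0) and state[3] == _U64(0):
        state[0] = _GOLDEN


@njit(cache=True, inline="always")
def next_uniform(state):
    """xoshiro256++ step; returns a 53-bit uniform deviate in [0, 1)."""
    result = (_rotl((state[0] + state[3]) & _U64(0xFFFFFFFFFFFFFFFF), _U64(23)) + state[0]) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    t = (state[1] << _U64(17)) & _U64(0xFFFFFFFFFFFFFFFF)
    state[2] ^= state[0]
    state[3] ^= state[1]
    state[1] ^= state[2]
    state[0] ^= state[3]
    state[2] ^= t
    state[3] = _rotl(state[3], _U64(45))
    return float(result >> _U64(11)) * _INV_2_53


class RandomStream:
    """Seeded uniform deviate stream with deterministic substreams.

    Identical ``(seed, stream_index)`` pairs reproduce identical
    sequences bit-for-bit, independent of how many deviates other
    substreams have consumed.
    """

    def __init__(self, seed: int, stream_index: int = 0):
        self.seed = int(seed)
        self.stream_index = int(stream_index)
        self._state = np.empty(4, dtype=np.uint64)
        init_state(self._state, self.seed, self.stream_index)

    def uniform(self) -> float:
        """Next deviate xi in [0, 1) at 53-bit resolution."""
        return next_uniform(self._state)

    def uniforms(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.float64)
        for i in range(n):
            out[i] = next_uniform(self._state)
        return out

    def substream(self, stream_index: int) -> "RandomStream":
        """Independent stream for e.g. one photon's trajectory."""
        return RandomStream(self.seed, stream_index)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(seed={self.seed}, stream_index={self.stream_index})"
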