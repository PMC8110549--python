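"""Configuration-code algebra for the 2^N asymptotic states of a star network.

In the hard-boundary, slow-plasticity limit every leaf of an N-leaf star
ends up either unsynchronized with the hub (both link weights ~ 0) or
synchronized through exactly one saturated directional link.  An asymptotic
configuration is therefore a length-N string over three symbols:

* ``0``   - leaf unsynchronized,
* ``1H``  - leaf synchronized and driving the hub (A_j = alpha, B_j = 0),
* ``1L``  - leaf synchronized and driven by the hub (A_j = 0, B_j = alpha).

Because the fastest oscillator of a synchronized cluster wins, at most one
link can point at the hub, and it must come from the fastest synchronized
leaf that is faster than the hub.  With the leaf frequencies in ascending
order and the hub frequency falling in interval ``k`` (k = 1: below all
leaves, ..., k = N+1: above all leaves), the n-th configuration
(n = 0..2^N-1) is built from the binary digits of n: write n as the bit
string (s_1..s_N) with s_1 the most significant bit, then among positions
j >= k carrying a 1 give the rightmost (largest j) the subscript H and all
remaining 1s the subscript L.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import NetworkParams

__all__ = [
    "Symbol",
    "ConfigCode",
    "ClassificationError",
    "hub_interval",
    "encode",
    "decode",
    "admissible_table",
    "code_to_state_vector",
    "classify_weights",
    "required_inequality",
]


class Symbol(str, enum.Enum):
    ZERO = "0"
    ONE_H = "1H"
    ONE_L = "1L"


class ClassificationError(ValueError):
    """A simulated weight pattern violates the predicted attractor structure."""


@dataclass(frozen=True)
class ConfigCode:
    """A length-N configuration code, optionally tagged with the hub interval k.

    The integer index ``n`` is recovered by stripping subscripts and reading
    the symbols as binary digits (s_1 = most significant).
    """

    symbols: tuple[Symbol, ...]
    k: int | None = None

    def __post_init__(self) -> None:
        symbols = tuple(Symbol(s) for s in self.symbols)
        object.__setattr__(self, "symbols", symbols)
        if len(symbols) < 1:
            raise ValueError("a code needs at least one symbol")
        n_hub = sum(s is Symbol.ONE_H for s in symbols)
        if n_hub > 1:
            raise ValueError(f"at most one hub-directed (1H) link allowed, got {n_hub}")
        if self.k is not None and not (1 <= self.k <= len(symbols) + 1):
            raise ValueError(f"hub interval k={self.k} out of range for N={len(symbols)}")

    @property
    def N(self) -> int:
        return len(self.symbols)

    @property
    def n(self) -> int:
        return decode(self)

    def __str__(self) -> str:
        return " ".join(s.value for s in self.symbols)

    @classmethod
    def from_string(cls, text: str, k: int | None = None) -> "ConfigCode":
        return cls(tuple(Symbol(tok) for tok in text.split()), k=k)


def hub_interval(omega0: float, omega: Sequence[float]) -> int:
    """Interval index k of the hub frequency among ascending leaf frequencies.

    k = 1 if omega0 < omega_1; k = j+1 if omega_j < omega0 < omega_{j+1};
    k = N+1 if omega0 > omega_N.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(np.diff(omega) <= 0):
        raise ValueError("leaf frequencies must be strictly ascending")
    if np.any(omega == omega0):
        raise ValueError("hub frequency coincides with a leaf frequency (degenerate)")
    return int(np.searchsorted(omega, omega0)) + 1


def encode(n: int, k: int, N: int) -> ConfigCode:
    """Build the code of the n-th asymptotic configuration for hub interval k."""
    if not 0 <= n < 2**N:
        raise ValueError(f"n={n} out of range for N={N}")
    if not 1 <= k <= N + 1:
        raise ValueError(f"k={k} out of range for N={N}")
    bits = [(n >> (N - j)) & 1 for j in range(1, N + 1)]  # s_j = d_{N-j}
    hub_pos = max((j for j in range(1, N + 1) if bits[j - 1] and j >= k), default=None)
    symbols = []
    for j in range(1, N + 1):
        if not bits[j - 1]:
            symbols.append(Symbol.ZERO)
        elif j == hub_pos:
            symbols.append(Symbol.ONE_H)
        else:
            symbols.append(Symbol.ONE_L)
    return ConfigCode(tuple(symbols), k=k)


def decode(code: ConfigCode) -> int:
    """Strip subscripts and read the code as a binary number."""
    n = 0
    for s in code.symbols:
        n = (n << 1) | (s is not Symbol.ZERO)
    return n


def admissible_table(N: int, k: int) -> list[ConfigCode]:
    """All 2^N admissible codes for hub interval k, ordered by index n."""
    return [encode(n, k, N) for n in range(2**N)]


def code_to_state_vector(code: ConfigCode, alpha: float = 1.0) -> np.ndarray:
    """Weight-space state vector R = (A_1..A_N, B_1..B_N) of a code.

    A_j = alpha iff s_j = 1H; B_j = alpha iff s_j = 1L; all else 0.
    """
    A = np.array([alpha if s is Symbol.ONE_H else 0.0 for s in code.symbols])
    B = np.array([alpha if s is Symbol.ONE_L else 0.0 for s in code.symbols])
    return np.concatenate([A, B])


def classify_weights(A, B, alpha: float, threshold_fraction: float = 0.5,
                     k: int | None = None) -> ConfigCode:
    """Label a simulated weight pattern with its configuration code.

    Per leaf: A_j above ``threshold_fraction * alpha`` -> 1H, else B_j above
    the threshold -> 1L, else 0.  A leaf with both weights above threshold
    contradicts the predicted attractor structure and raises
    :class:`ClassificationError` (as does a pattern with two hub-directed
    links, via the ConfigCode invariant).
    """
    A = np.atleast_1d(np.asarray(A, dtype=float))
    B = np.atleast_1d(np.asarray(B, dtype=float))
    thr = threshold_fraction * alpha
    both = (A > thr) & (B > thr)
    if np.any(both):
        raise ClassificationError(
            f"leaves {np.flatnonzero(both).tolist()} have both weights above "
            f"{thr:.3g}; pattern does not match any predicted configuration"
        )
    symbols = tuple(
        Symbol.ONE_H if a > thr else (Symbol.ONE_L if b > thr else Symbol.ZERO)
        for a, b in zip(A, B)
    )
    try:
        return ConfigCode(symbols, k=k)
    except ValueError as exc:
        raise ClassificationError(str(exc)) from exc


def required_inequality(code: ConfigCode, params: "NetworkParams") -> bool:
    """Whether ``code`` is realizable for the given network parameters.

    Requires alpha > |omega0 - omega_j| for every leaf (existence of the
    synchronized two-oscillator state) and that the hub-directed link, if
    any, sits where the code-construction rule puts it for the parameters'
    hub interval.
    """
    if code.N != params.N:
        raise ValueError("code and params disagree on N")
    if not np.all(params.alpha > np.abs(params.detunings)):
        return False
    k = hub_interval(params.omega0, params.omega)
    return encode(decode(code), k, code.N).symbols == code.symbols
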