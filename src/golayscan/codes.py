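"""Binary excitation codes: Golay complementary pairs and baselines.

A Golay complementary pair is two equal-length sequences over {-1, +1}
whose aperiodic autocorrelations sum to a Kronecker delta: 2N at lag 0
and exactly zero at every other lag.  Correlating a received trace with
each transmitted sequence and summing therefore compresses the coded
pulse into a single sidelobe-free main lobe of height 2N — the property
that makes coded excitation attractive for strongly attenuating,
air-coupled paths.

Everything in this module is exact integer arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CodePair",
    "Code",
    "generate_golay_pair",
    "complementary_autocorrelation",
    "is_complementary",
    "barker7",
    "burst",
]

_MAX_ORDER = 16

#: The length-7 Barker sequence (unique up to symmetry); peak-to-sidelobe
#: ratio 7:1, the best achievable for a single binary code of this length.
_BARKER7 = (1, 1, 1, -1, -1, 1, -1)


def _as_pm1(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isin(arr, (-1, 1))):
        raise ValueError(f"{name} must contain only +1 and -1")
    return arr


@dataclass(frozen=True)
class CodePair:
    """A complementary pair of ±1 sequences of length ``2**order``."""

    a: np.ndarray
    b: np.ndarray
    order: int

    def __post_init__(self):
        object.__setattr__(self, "a", _as_pm1(self.a, "a"))
        object.__setattr__(self, "b", _as_pm1(self.b, "b"))
        n = 2**self.order
        if len(self.a) != n or len(self.b) != n:
            raise ValueError(f"sequences must have length 2**order = {n}")

    @property
    def n(self) -> int:
        """Sequence length N."""
        return len(self.a)


@dataclass(frozen=True)
class Code:
    """A single excitation code (Golay half, Barker, or uncoded burst)."""

    values: np.ndarray
    family: str = "burst"

    _FAMILIES = ("golay_a", "golay_b", "barker", "burst")

    def __post_init__(self):
        object.__setattr__(self, "values", _as_pm1(self.values, "values"))
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown code family {self.family!r}")

    def to_csv_line(self) -> str:
        return ",".join(str(int(v)) for v in self.values)

    @classmethod
    def from_csv_line(cls, line: str, family: str = "burst") -> "Code":
        values = [int(tok) for tok in line.strip().split(",") if tok.strip()]
        return cls(values=np.asarray(values), family=family)

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "values": [int(v) for v in self.values]}
        )

    @classmethod
    def from_json(cls, text: str) -> "Code":
        obj = json.loads(text)
        return cls(values=np.asarray(obj["values"]), family=obj["family"])


def generate_golay_pair(order: int) -> CodePair:
    """Generate the Golay complementary pair of length ``2**order``.

    Uses the standard append recursion ``A' = A‖B``, ``B' = A‖(−B)``
    starting from ``A = B = (1)``.  Every iterate is complementary, so
    the summed autocorrelation is ``2N·δ`` exactly.

    Parameters
    ----------
    order : int
        Doubling depth ``k``; the pair has length ``N = 2**k``.
        Must satisfy ``0 <= order <= 16``.
    """
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise ValueError("order must be an integer")
    if not 0 <= order <= _MAX_ORDER:
        raise ValueError(f"order must be in [0, {_MAX_ORDER}], got {order}")
    a = np.array([1], dtype=np.int64)
    b = np.array([1], dtype=np.int64)
    for _ in range(order):
        a, b = np.concatenate([a, b]), np.concatenate([a, -b])
    return CodePair(a=a, b=b, order=int(order))


def complementary_autocorrelation(pair: CodePair) -> np.ndarray:
    """Sum of the aperiodic autocorrelations of the two sequences.

    Returns an integer array over lags ``-(N-1) … (N-1)`` (length
    ``2N-1``, zero lag at index ``N-1``).  For a valid complementary
    pair this is ``2N`` at the center and zero elsewhere.
    """
    acf_a = np.correlate(pair.a, pair.a, mode="full")
    acf_b = np.correlate(pair.b, pair.b, mode="full")
    return acf_a + acf_b


def is_complementary(a, b) -> bool:
    """True iff ``a`` and ``b`` form a Golay complementary pair.

    Checks the summed aperiodic autocorrelation against ``2N·δ`` in
    exact integer arithmetic.
    """
    a = _as_pm1(a, "a")
    b = _as_pm1(b, "b")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    acf = np.correlate(a, a, "full") + np.correlate(b, b, "full")
    n = len(a)
    expected = np.zeros(2 * n - 1, dtype=np.int64)
    expected[n - 1] = 2 * n
    return bool(np.array_equal(acf, expected))


def barker7() -> Code:
    """The length-7 Barker code (peak 7, max sidelobe magnitude 1)."""
    return Code(values=np.asarray(_BARKER7), family="barker")


def burst(n: int) -> Code:
    """Uncoded multi-pulse baseline: ``n`` chips of +1.

    Its autocorrelation is a triangle with sidelobes up to ``n - 1``,
    which is exactly the resolution problem coded excitation removes.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"burst length must be a positive integer, got {n}")
    return Code(values=np.ones(int(n), dtype=np.int64), family="burst")
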