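"""NK payoff landscapes with tunable ruggedness.

A solution is a vector of ``n_elements`` bits; internally every solution is
encoded as an integer code in ``[0, 2**n_elements)`` with element ``i``
stored in bit ``i`` of the code (element 0 is the least-significant bit).
Each element ``i`` contributes a value ``f_i`` drawn uniformly from [0, 1]
that depends on the joint state of the element itself and ``k_interactions``
randomly chosen partner elements; the raw payoff of a solution is the mean
contribution over elements.  ``k_interactions = 0`` gives a smooth,
single-peaked landscape (a simple task); larger values give rugged
landscapes with many local optima (complex tasks).

Because the payoff is normalized by the enumerated global maximum and then
sharpened by raising it to a power (default 8), building a landscape
enumerates all ``2**n_elements`` solutions once and caches the full
transformed payoff table, making every later payoff evaluation an O(1)
lookup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "CapacityError",
    "NKLandscape",
    "SolutionLike",
    "bits_to_code",
    "code_to_bits",
    "generate_landscape",
]

#: hard guard on exhaustive enumeration (2**24 solutions)
MAX_ENUM_BITS = 24

DEFAULT_EXPONENT = 8.0

SolutionLike = Union[int, Sequence[int], np.ndarray]


class CapacityError(ValueError):
    """Landscape too large for exhaustive enumeration."""


def bits_to_code(bits: Sequence[int] | np.ndarray) -> int:
    """Pack a bit vector into an integer code (element 0 = LSB)."""
    bits = np.asarray(bits)
    if bits.ndim != 1:
        raise ValueError("bit vector must be one-dimensional")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("solution elements must be 0 or 1")
    return int((bits.astype(np.int64) << np.arange(bits.size)).sum())


def code_to_bits(code: int, n_elements: int) -> np.ndarray:
    """Unpack an integer code into a length-``n_elements`` bit vector."""
    code = int(code)
    if not 0 <= code < (1 << n_elements):
        raise ValueError(f"code {code} out of range for {n_elements} elements")
    return (code >> np.arange(n_elements)) & 1


def _as_code(solution: SolutionLike, n_elements: int) -> int:
    if isinstance(solution, (int, np.integer)):
        code = int(solution)
        if not 0 <= code < (1 << n_elements):
            raise ValueError(f"solution code {code} out of range")
        return code
    bits = np.asarray(solution)
    if bits.size != n_elements:
        raise ValueError(
            f"solution has {bits.size} elements, landscape has {n_elements}"
        )
    return bits_to_code(bits)


@dataclass
class NKLandscape:
    """One skill class's payoff function.

    Attributes
    ----------
    n_elements
        Number of binary elements per solution.
    k_interactions
        Number of partner elements each element's contribution depends on.
    partners
        ``(n_elements, k_interactions)`` integer array; row ``i`` holds the
        ordered partner indices of element ``i`` (distinct, never ``i``).
    contributions
        ``(n_elements, 2**(k_interactions+1))`` array of uniform [0, 1]
        contribution values.  The lookup key for element ``i`` packs the
        element's own state into bit 0 and the partners' states into bits
        1..k, in ``partners`` row order.
    exponent
        Sharpening power applied to the normalized payoff (default 8).
    seed
        Seed the landscape was generated from (None for hand-built tables).
    """

    n_elements: int
    k_interactions: int
    partners: np.ndarray
    contributions: np.ndarray
    exponent: float = DEFAULT_EXPONENT
    seed: int | None = None
    # caches, filled in __post_init__ by exhaustive enumeration
    raw_table: np.ndarray = field(init=False, repr=False)
    payoff_table: np.ndarray = field(init=False, repr=False)
    max_raw: float = field(init=False)

    def __post_init__(self) -> None:
        n, k = int(self.n_elements), int(self.k_interactions)
        if n < 1:
            raise ValueError("n_elements must be >= 1")
        if not 0 <= k <= n - 1:
            raise ValueError("k_interactions must satisfy 0 <= k <= n_elements - 1")
        if n > MAX_ENUM_BITS:
            raise CapacityError(
                f"n_elements={n} exceeds enumeration guard ({MAX_ENUM_BITS})"
            )
        self.partners = np.asarray(self.partners, dtype=np.int64).reshape(n, k)
        self.contributions = np.asarray(self.contributions, dtype=np.float64)
        if self.contributions.shape != (n, 1 << (k + 1)):
            raise ValueError(
                f"contributions must have shape {(n, 1 << (k + 1))}, "
                f"got {self.contributions.shape}"
            )
        if ((self.contributions < 0) | (self.contributions > 1)).any():
            raise ValueError("contribution values must lie in [0, 1]")
        for i in range(n):
            row = self.partners[i]
            if len(set(row.tolist())) != k or i in row:
                raise ValueError(f"element {i}: partners must be distinct and != i")
        self.raw_table = self._enumerate_raw()
        self.max_raw = float(self.raw_table.max())
        if self.max_raw <= 0:
            raise ValueError("max raw payoff must be positive")
        self.payoff_table = (self.raw_table / self.max_raw) ** float(self.exponent)
        # the raw argmax maps to exactly 1 regardless of float rounding
        self.payoff_table[self.raw_table == self.max_raw] = 1.0

    # -- construction -----------------------------------------------------

    def _enumerate_raw(self) -> np.ndarray:
        n = self.n_elements
        codes = np.arange(1 << n, dtype=np.int64)
        raw = np.zeros(1 << n)
        for i in range(n):
            key = (codes >> i) & 1
            for j, p in enumerate(self.partners[i]):
                key = key | (((codes >> int(p)) & 1) << (j + 1))
            raw += self.contributions[i][key]
        raw /= n
        return raw

    # -- evaluation --------------------------------------------------------

    def raw_payoff(self, solution: SolutionLike) -> float:
        """Mean element contribution of ``solution`` (in [0, 1])."""
        return float(self.raw_table[_as_code(solution, self.n_elements)])

    def payoff(self, solution: SolutionLike) -> float:
        """Normalized, sharpened payoff ``(raw / max_raw) ** exponent``."""
        return float(self.payoff_table[_as_code(solution, self.n_elements)])

    def global_optimum(self) -> int:
        """Code of the raw-payoff argmax (smallest code on ties)."""
        return int(np.argmax(self.raw_table))

    def count_local_optima(self) -> int:
        """Number of solutions strictly better than all 1-flip neighbours."""
        codes = np.arange(1 << self.n_elements, dtype=np.int64)
        is_peak = np.ones(codes.size, dtype=bool)
        for j in range(self.n_elements):
            is_peak &= self.raw_table > self.raw_table[codes ^ (1 << j)]
        return int(is_peak.sum())

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize generation inputs (tables are rebuilt on load)."""
        doc = {
            "n_elements": self.n_elements,
            "k_interactions": self.k_interactions,
            "exponent": self.exponent,
            "seed": self.seed,
            "partners": self.partners.tolist(),
            "contributions": self.contributions.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NKLandscape":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            n_elements=doc["n_elements"],
            k_interactions=doc["k_interactions"],
            partners=np.asarray(doc["partners"], dtype=np.int64),
            contributions=np.asarray(doc["contributions"], dtype=np.float64),
            exponent=doc["exponent"],
            seed=doc["seed"],
        )


def generate_landscape(
    n_elements: int,
    k_interactions: int,
    seed: int,
    exponent: float = DEFAULT_EXPONENT,
) -> NKLandscape:
    """Draw a random NK landscape.

    Partner sets are sampled uniformly without replacement from the other
    elements; contribution values are i.i.d. uniform on [0, 1].  The payoff
    table is precomputed by exhaustive enumeration.
    """
    n, k = int(n_elements), int(k_interactions)
    if n < 1 or not 0 <= k <= n - 1:
        raise ValueError(
            f"invalid NK parameters (n_elements={n}, k_interactions={k})"
        )
    if n > MAX_ENUM_BITS:
        raise CapacityError(
            f"n_elements={n} exceeds enumeration guard ({MAX_ENUM_BITS})"
        )
    rng = np.random.default_rng(seed)
    partners = np.empty((n, k), dtype=np.int64)
    others = np.arange(n)
    for i in range(n):
        pool = others[others != i]
        partners[i] = rng.choice(pool, size=k, replace=False)
    contributions = rng.random((n, 1 << (k + 1)))
    return NKLandscape(
        n_elements=n,
        k_interactions=k,
        partners=partners,
        contributions=contributions,
        exponent=exponent,
        seed=int(seed),
    )
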