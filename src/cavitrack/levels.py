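"""Cavitation level schemes: binning a trial's grand-total count into an ordinal level.

Four schemes are defined.  Schemes 1-2 are "data-driven" (bins follow the
observed count distribution, so every level is populated by at least one
trial); schemes 3-4 are "distribution-driven" (regular bin widths,
regardless of which counts actually occurred).  Bins are left-open /
right-closed: level 1 is n <= b1, level l is b_{l-1} < n <= b_l, and the
top level is unbounded above.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass

__all__ = ["CavitationScheme", "scheme", "assign_level", "SCHEME_IDS"]

_SCHEME_BOUNDS: dict[int, tuple[int, ...]] = {
    1: (5, 20),
    2: (1, 5, 10, 25, 75),
    3: (1, 5, 10, 25, 50, 100),
    4: (1, 5, 10, 15, 20, 30, 40, 50),
}

SCHEME_IDS: tuple[int, ...] = (1, 2, 3, 4)

#: Shock overpressure (kPa) under which the level definitions were drawn up.
#: Recorded as provenance metadata only; it plays no computational role.
REFERENCE_OVERPRESSURE_KPA: float = 207.0


@dataclass(frozen=True)
class CavitationScheme:
    """Ordered count bins mapping a grand total n to a level 1..n_levels."""

    scheme_id: int
    bounds: tuple[int, ...]  # strictly increasing upper bounds b1 < ... < b_{L-1}

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("bounds must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.bounds) + 1

    def to_json(self) -> str:
        """Export (scheme_id, bounds, level count) for report provenance."""
        return json.dumps(
            {
                "scheme_id": self.scheme_id,
                "bounds": list(self.bounds),
                "n_levels": self.n_levels,
            }
        )


def scheme(scheme_id: int) -> CavitationScheme:
    """Return one of the four predefined cavitation schemes."""
    try:
        bounds = _SCHEME_BOUNDS[scheme_id]
    except KeyError:
        raise ValueError(f"unknown cavitation scheme {scheme_id!r}; valid ids: 1-4") from None
    return CavitationScheme(scheme_id=scheme_id, bounds=bounds)


def assign_level(n: int, scheme: CavitationScheme) -> int:
    """Cavitation level of a grand-total bubble count ``n`` under ``scheme``.

    Intervals are left-open, right-closed, so a count equal to a bound
    belongs to the lower level.
    """
    if isinstance(n, bool) or int(n) != n:
        raise ValueError("n must be an integer bubble count")
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    return bisect_left(scheme.bounds, n) + 1
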