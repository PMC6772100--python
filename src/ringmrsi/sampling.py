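"""Ring undersampling patterns, retrospective decimation, and stage ladders.

Acceleration is expressed per ring: each ring costs one TR per temporal
interleaf, so the effective acceleration factor is the ratio of total to
measured rings.  Variable-density patterns keep an innermost fully sampled
core (default five rings) and decimate only the periphery; among the outer
rings every ``nominal_R``-th is kept after skipping the first
``nominal_R - 1`` (this phase convention makes patterns of successive
powers of two nest, which the recursive reconstruction ladder relies on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kspace import RingKSpace

__all__ = ["UndersamplingPattern", "make_pattern", "decimate", "stage_patterns"]


@dataclass(frozen=True)
class UndersamplingPattern:
    n_rings: int
    measured: np.ndarray  # bool per ring
    nominal_R: int
    n_full_inner: int

    @property
    def n_measured(self) -> int:
        return int(np.count_nonzero(self.measured))

    @property
    def effective_R(self) -> float:
        """Total rings over measured rings, rounded to 2 decimals."""
        return round(self.n_rings / self.n_measured, 2)

    @property
    def effective_R_exact(self) -> float:
        return self.n_rings / self.n_measured

    @property
    def missing(self) -> np.ndarray:
        return ~self.measured

    def to_dict(self) -> dict:
        return {
            "n_rings": self.n_rings,
            "nominal_R": self.nominal_R,
            "n_full_inner": self.n_full_inner,
            "measured": [int(m) for m in self.measured],
            "effective_R": self.effective_R,
        }


def make_pattern(n_rings: int, nominal_R: int, n_full_inner: int = 0) -> UndersamplingPattern:
    """Build a constant- (core 0) or variable-density ring pattern.

    Rings ``0 .. n_full_inner-1`` are always measured; among the remaining
    outer rings every ``nominal_R``-th is kept, starting after skipping
    ``nominal_R - 1``.  E.g. 32 rings / R=2 / core 5 measures 18 rings
    (effective R 1.78) and R=4 / core 5 measures 11 (effective R 2.91).
    """
    if nominal_R < 1:
        raise ValueError(f"nominal_R must be >= 1, got {nominal_R}")
    if not 0 <= n_full_inner < n_rings:
        raise ValueError(
            f"n_full_inner must be in [0, n_rings), got {n_full_inner} for "
            f"{n_rings} rings"
        )
    n_outer = n_rings - n_full_inner
    if nominal_R > n_outer:
        raise ValueError(
            f"nominal_R={nominal_R} leaves no measured outer ring "
            f"({n_outer} outer rings)"
        )
    measured = np.zeros(n_rings, dtype=bool)
    measured[:n_full_inner] = True
    m = np.arange(n_outer)
    measured[n_full_inner:] = (m + 1) % nominal_R == 0
    return UndersamplingPattern(
        n_rings=int(n_rings),
        measured=measured,
        nominal_R=int(nominal_R),
        n_full_inner=int(n_full_inner),
    )


def decimate(ksp: RingKSpace, pattern: UndersamplingPattern) -> RingKSpace:
    """Retrospectively discard the rings a pattern marks as missing.

    Pure restriction: data on missing rings is zeroed, measured rings pass
    through untouched (no scaling); idempotent.
    """
    if pattern.n_rings != ksp.traj.n_rings:
        raise ValueError(
            f"pattern has {pattern.n_rings} rings but k-space has "
            f"{ksp.traj.n_rings}"
        )
    out = ksp.copy()
    out.data[:, pattern.missing] = 0
    out.measured_rings = pattern.measured.copy()
    return out


def stage_patterns(pattern: UndersamplingPattern) -> list[UndersamplingPattern]:
    """Recursion ladder of successively denser patterns ending fully sampled.

    R=2 -> [full]; R=4 -> [R=2 pattern, full]; R=8 -> [R=4, R=2, full].
    Each stage's measured set strictly contains the previous stage's, and the
    fully sampled core size is preserved throughout.
    """
    if pattern.nominal_R not in (2, 4, 8):
        raise ValueError(
            f"recursion ladder supports nominal_R in {{2, 4, 8}}, got "
            f"{pattern.nominal_R}"
        )
    ladder = []
    r = pattern.nominal_R // 2
    while r >= 1:
        ladder.append(make_pattern(pattern.n_rings, r, pattern.n_full_inner))
        r //= 2
    return ladder
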