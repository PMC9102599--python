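"""Discrete organelle size-class distributions.

A :class:`SizeDistribution` holds probability mass over integer size
classes ``n = 1, 2, ..., n_max`` (number of VWF quanta for WPBs, number of
mini-stacks for Golgi fragments), plus an explicit ``tail_mass`` for the
probability a theoretical model assigns beyond ``n_max``.  Keeping the tail
explicit — rather than silently renormalizing the truncated head — means
every model distribution sums to one analytically and cumulative
distribution functions are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SizeDistribution"]

#: absolute tolerance for "sums to one" checks
NORM_ATOL = 1e-9


@dataclass(frozen=True)
class SizeDistribution:
    """Probability mass (or counts, normalized) over size classes 1..n_max.

    Parameters
    ----------
    mass
        Probability per class; ``mass[i]`` is the mass of class ``i + 1``.
    tail_mass
        Mass assigned by a theoretical model to classes ``> n_max``.
        Zero for empirical distributions.
    total_count
        Number of observations behind an empirical distribution, if any.
    """

    mass: np.ndarray
    tail_mass: float = 0.0
    total_count: int | None = None
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.ndim != 1 or m.size == 0:
            raise ValidationError("mass must be a non-empty 1-D array")
        if np.any(m < -NORM_ATOL):
            raise ValidationError("mass values must be non-negative")
        if self.tail_mass < -NORM_ATOL:
            raise ValidationError("tail_mass must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_max(self) -> int:
        return int(self.mass.size)

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    def total_mass(self) -> float:
        return float(self.mass.sum() + self.tail_mass)

    def is_normalized(self, atol: float = NORM_ATOL) -> bool:
        return abs(self.total_mass() - 1.0) <= atol

    def require_normalized(self, atol: float = 1e-6) -> None:
        if not self.is_normalized(atol):
            raise ValidationError(
                f"distribution mass sums to {self.total_mass():.12g}, not 1"
            )

    # -- derived quantities ---------------------------------------------
    def cdf(self) -> np.ndarray:
        """Cumulative mass at classes 1..n_max (the tail is the open class
        beyond ``n_max``, where every CDF reaches 1)."""
        return np.cumsum(self.mass)

    def prob(self, n: int) -> float:
        """Mass of class ``n`` (0 beyond ``n_max``; the tail is not a class)."""
        if n < 1:
            raise ValidationError("size classes start at 1")
        return float(self.mass[n - 1]) if n <= self.n_max else 0.0

    def mode(self) -> int:
        return int(np.argmax(self.mass) + 1)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_counts(cls, counts: Mapping[int, int] | np.ndarray) -> "SizeDistribution":
        """Empirical distribution from integer class counts.

        Accepts a ``{class: count}`` mapping or a dense array indexed from
        class 1.  Mass is ``count / total``; because counts are integers the
        masses sum to one exactly in rational arithmetic.
        """
        if isinstance(counts, Mapping):
            if not counts:
                raise ValidationError("empty count mapping")
            n_max = max(int(k) for k in counts)
            if min(int(k) for k in counts) < 1:
                raise ValidationError("size classes start at 1")
            dense = np.zeros(n_max, dtype=np.int64)
            for k, v in counts.items():
                if v < 0:
                    raise ValidationError("counts must be non-negative")
                dense[int(k) - 1] = int(v)
        else:
            dense = np.asarray(counts, dtype=np.int64)
        total = int(dense.sum())
        if total <= 0:
            raise ValidationError("counts sum to zero")
        return cls(mass=dense / total, tail_mass=0.0, total_count=total, counts=dense)

    # -- export ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"size_class": self.classes, "frequency": self.mass})
        if self.counts is not None:
            df.insert(1, "count", self.counts)
        return df

    def to_dict(self) -> dict:
        d = {
            "classes": self.classes.tolist(),
            "mass": self.mass.tolist(),
            "tail_mass": float(self.tail_mass),
        }
        if self.total_count is not None:
            d["total_count"] = int(self.total_count)
        return d

    def extended(self, n_max: int) -> "SizeDistribution":
        """Pad with zero-mass classes up to ``n_max`` (tail unchanged)."""
        if n_max < self.n_max:
            raise ValidationError("cannot shrink with extended(); use lumped()")
        pad = np.zeros(n_max - self.n_max)
        return SizeDistribution(
            np.concatenate([self.mass, pad]), self.tail_mass, self.total_count
        )

    def lumped(self, n_max: int) -> "SizeDistribution":
        """Lump all classes above ``n_max`` into the tail."""
        if n_max >= self.n_max:
            return self.extended(n_max)
        head = self.mass[:n_max].copy()
        tail = float(self.mass[n_max:].sum() + self.tail_mass)
        return SizeDistribution(head, tail, self.total_count)
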