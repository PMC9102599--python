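"""Kolmogorov–Smirnov grid fitting of ribbon-model parameters.

The fitting procedure is deliberately the simple two-step scheme the
science calls for:

1.  ``fit_p_tail`` — the occupancy ``p`` is identified from the observed
    distribution *conditioned on n >= 2*.  Under the instability model the
    conditional tail is a geometric distribution starting at 2 regardless
    of ``alpha``, so ``p`` can be fit first, by minimizing the KS distance
    over a fine ``p`` grid, without any assumption about the 1Q class.
2.  ``alpha`` is then fixed algebraically from the observed 1Q frequency
    (``alpha_from_f1``), reproducing it exactly.

``fit_shared_alpha`` extends this to a multi-condition series (e.g. a VWF
knockdown titration): each condition gets its own ``p``, and a single
shared ``alpha`` is the WPB-count-weighted mean of the per-condition
inversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distributions import SizeDistribution
from .errors import UnfittableError, ValidationError
from .models import alpha_from_f1, instability_model

__all__ = [
    "DEFAULT_P_GRID",
    "FitResult",
    "ks_distance",
    "fit_p_tail",
    "fit_instability",
    "fit_shared_alpha",
]

#: p searched at the resolution the fitted values are reported at (4 d.p.)
DEFAULT_P_GRID = np.linspace(0.0, 0.9999, 10000)


@dataclass
class FitResult:
    """Outcome of a KS grid fit."""

    family: str
    params: dict
    ks_distance: float
    grid: dict = field(default_factory=dict)
    predicted: SizeDistribution | None = None
    total_count: int | None = None
    warnings: list[str] = field(default_factory=list)
    conditions: dict[str, "FitResult"] = field(default_factory=dict)

    @property
    def alpha_exceeds_one(self) -> bool:
        a = self.params.get("alpha")
        return a is not None and a > 1.0

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "ks_distance": float(self.ks_distance),
            "grid": self.grid,
            "warnings": list(self.warnings),
        }
        if self.total_count is not None:
            d["total_count"] = int(self.total_count)
        if self.conditions:
            d["conditions"] = {k: v.to_dict() for k, v in self.conditions.items()}
        return d


def _padded_cdf(dist: SizeDistribution, n_max: int) -> np.ndarray:
    """CDF evaluated at classes 1..n_max; beyond the distribution's own
    support the CDF is flat at 1 - tail_mass (the tail is the open final
    class, where both CDFs being compared reach 1)."""
    cdf = dist.cdf()
    if dist.n_max >= n_max:
        return cdf[:n_max]
    return np.concatenate([cdf, np.full(n_max - dist.n_max, cdf[-1])])


def ks_distance(a: SizeDistribution, b: SizeDistribution) -> float:
    """Maximal absolute difference between the two CDFs.

    Both inputs must be normalized (head + tail = 1).  Tail mass is treated
    as a final open class shared by both distributions, so the comparison
    runs over classes 1..max(n_max_a, n_max_b)."""
    a.require_normalized()
    b.require_normalized()
    n = max(a.n_max, b.n_max)
    return float(np.max(np.abs(_padded_cdf(a, n) - _padded_cdf(b, n))))


def _conditional_tail(observed: SizeDistribution) -> tuple[np.ndarray, float]:
    """Observed masses over classes >= 2, renormalized; returns
    (mass over classes 2..n_max, conditional tail mass)."""
    rest = observed.mass[1:]
    total = float(rest.sum() + observed.tail_mass)
    if total <= 0:
        raise UnfittableError(
            "observed distribution has no mass above class 1; p is unidentifiable"
        )
    return rest / total, observed.tail_mass / total


def fit_p_tail(
    observed: SizeDistribution, grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Fit occupancy ``p`` to the n >= 2 conditional of ``observed``.

    The model conditional is the geometric tail shifted to start at 2,
    P(n | n >= 2) = p^(n-2) (1-p); both sides are proper conditional
    distributions, so the KS distance is well defined.  Returns the grid
    ``p`` minimizing the KS distance (ties broken toward smaller p) and
    that minimal distance.
    """
    observed.require_normalized()
    if grid is None:
        grid = DEFAULT_P_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any((grid < 0) | (grid >= 1)):
        raise ValidationError("p grid must be non-empty and lie in [0, 1)")
    if observed.n_max < 2:
        raise UnfittableError("observed distribution has no classes above 1")
    cond_mass, _ = _conditional_tail(observed)
    obs_cdf = np.cumsum(cond_mass)  # at classes 2..n_max
    n = np.arange(2, observed.n_max + 1)
    # conditional model CDF at class n: 1 - p^(n-1)
    model_cdf = 1.0 - grid[:, None] ** (n - 1)[None, :]
    ks = np.max(np.abs(model_cdf - obs_cdf[None, :]), axis=1)
    best = int(np.argmin(ks))  # argmin returns the first minimum: smallest p
    return float(grid[best]), float(ks[best])


def fit_instability(
    observed: SizeDistribution,
    grid: np.ndarray | None = None,
    n_max: int = 100,
) -> FitResult:
    """Two-step instability-model fit: p from the n>=2 tail, alpha from the
    observed 1Q frequency."""
    observed.require_normalized()
    if observed.mass[0] <= 0:
        raise UnfittableError("observed distribution has no 1Q mass; alpha undefined")
    p, ks_tail = fit_p_tail(observed, grid)
    if p == 0.0:
        raise UnfittableError("tail fit drove p to 0; alpha inversion undefined")
    f1 = float(observed.mass[0])
    alpha = alpha_from_f1(p, f1)
    predicted = instability_model(p, alpha, n_max=max(n_max, observed.n_max))
    warnings = []
    if alpha > 1.0:
        warnings.append(
            f"alpha={alpha:.4f} > 1: data outside the 1Q-instability regime"
        )
    used = DEFAULT_P_GRID if grid is None else np.asarray(grid)
    return FitResult(
        family="instability",
        params={"p": p, "alpha": alpha},
        ks_distance=ks_distance(observed, predicted),
        grid={"p_min": float(used.min()), "p_max": float(used.max()),
              "n_points": int(used.size)},
        predicted=predicted,
        total_count=observed.total_count,
        warnings=warnings,
    )


def fit_shared_alpha(
    observed: dict[str, SizeDistribution] | Sequence[tuple[str, SizeDistribution]],
    grid: np.ndarray | None = None,
    n_max: int = 100,
) -> FitResult:
    """Multi-condition fit with per-condition p and one shared alpha.

    Each observed distribution must carry ``total_count``; the shared alpha
    is sum_i alpha_i N_i / sum_i N_i with N_i the condition WPB counts.
    Per-condition predictions use (p_i, shared alpha).
    """
    items = list(observed.items()) if isinstance(observed, dict) else list(observed)
    if len(items) < 2:
        raise ValidationError(
            "shared-alpha fitting needs >= 2 conditions; use fit_instability"
        )
    alphas, counts, subfits = [], [], {}
    for label, dist in items:
        if dist.total_count is None or dist.total_count <= 0:
            raise ValidationError(
                f"condition {label!r} lacks a positive total_count for weighting"
            )
        sub = fit_instability(dist, grid=grid, n_max=n_max)
        subfits[label] = sub
        alphas.append(sub.params["alpha"])
        counts.append(dist.total_count)
    alphas = np.asarray(alphas)
    counts = np.asarray(counts, dtype=float)
    shared = float(np.sum(alphas * counts) / counts.sum())
    warnings = []
    if shared > 1.0:
        warnings.append(f"shared alpha={shared:.4f} > 1: outside instability regime")
    total_ks = 0.0
    for (label, dist), sub in zip(items, subfits.values()):
        p_i = sub.params["p"]
        predicted = instability_model(p_i, shared, n_max=max(n_max, dist.n_max))
        ks_i = ks_distance(dist, predicted)
        sub.conditions = {}
        sub.params = {"p": p_i, "alpha": shared, "alpha_unshared": sub.params["alpha"]}
        sub.predicted = predicted
        sub.ks_distance = ks_i
        total_ks += ks_i * dist.total_count
    total_n = counts.sum()
    return FitResult(
        family="instability-shared-alpha",
        params={"alpha": shared},
        ks_distance=total_ks / total_n,  # count-weighted mean condition KS
        grid=subfits[items[0][0]].grid,
        total_count=int(total_n),
        warnings=warnings,
        conditions=subfits,
    )
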