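"""Closed-form WPB size distributions under hypothesized Golgi-ribbon organizations.

Each model predicts the distribution of WPB lengths, in units of VWF
quanta, generated at the trans-Golgi network when mini-stacks of a Golgi
with a given lateral organization are occupied by VWF quanta with
probability ``p`` and runs of occupied neighbors co-package into one
granule:

``geometric_model``
    A single effectively infinite linear ribbon of identical mini-stacks.
    Run lengths are geometric, ``P(N = n) = p**(n-1) * (1-p)``.
``uniform_mixture_model`` / ``mixture_model``
    Occupancy varies from cell to cell; pooling geometric distributions
    over a distribution of ``p``.  A uniform ``p`` on [0, 1] gives the
    closed form ``P(N = n) = 1 / (n (n+1))``.
``segment_run_model``
    The Golgi as a collection of short independent mini-ribbons of ``L``
    mini-stacks; WPB proportions follow run combinatorics on a finite
    Bernoulli segment.
``dimers_plus_ribbon_model``
    A fraction ``q`` of mini-stacks circulates as free dimers, the rest
    forms a long linear ribbon.
``instability_model``
    A long ribbon whose single-quantum (1Q) products are selectively
    depleted, e.g. by basal exocytosis; ``alpha`` < 1 measures their
    relative instability (steady-state abundance factor ratio).

All functions return :class:`~wpbribbon.distributions.SizeDistribution`
with an analytically exact tail beyond the truncation class ``n_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import SizeDistribution
from .errors import DegenerateParameterError, ValidationError

__all__ = [
    "RibbonModelParams",
    "geometric_model",
    "uniform_mixture_model",
    "mixture_model",
    "uniform_p_grid",
    "segment_run_model",
    "dimers_plus_ribbon_model",
    "instability_model",
    "alpha_from_f1",
]

DEFAULT_N_MAX = 100


@dataclass
class RibbonModelParams:
    """Bundle of ribbon-model parameters, mainly for CLI/config plumbing.

    p      : mini-stack occupancy probability (proxy for VWF expression)
    alpha  : relative instability of 1Q-WPBs (= beta'/beta, <= 1 in the
             physical regime; 1 means no selective depletion)
    q      : proportion of mini-stacks existing as free dimers
    L      : mini-ribbon segment length, in mini-stacks
    p_mixture : optional (values, weights) discrete distribution over p
    """

    p: float = 0.5
    alpha: float = 1.0
    q: float = 0.0
    L: int = 3
    p_mixture: tuple[np.ndarray, np.ndarray] | None = None
    n_max: int = DEFAULT_N_MAX

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.alpha <= 0.0:
            raise ValidationError("alpha must be positive")
        if self.L < 1:
            raise ValidationError("segment length L must be >= 1")
        if self.p_mixture is not None:
            _, w = self.p_mixture
            if abs(float(np.sum(w)) - 1.0) > 1e-9:
                raise ValidationError("p_mixture weights must sum to 1")


def _check_p(p: float, *, open_left: bool = False, open_right: bool = True) -> None:
    lo_ok = p > 0 if open_left else p >= 0
    hi_ok = p < 1 if open_right else p <= 1
    if not (lo_ok and hi_ok):
        raise ValidationError(f"occupancy p={p} outside the valid range")


def geometric_model(p: float, n_max: int = DEFAULT_N_MAX) -> SizeDistribution:
    """Single infinite linear-array ribbon: P(N=n) = p^(n-1) (1-p).

    At ``p = 0`` every occupied mini-stack is isolated and all WPBs are
    single-quantum.  ``p = 1`` is degenerate (one infinite granule).
    """
    if p == 1:
        raise DegenerateParameterError("p=1: the whole ribbon is one infinite WPB")
    _check_p(p)
    n = np.arange(1, n_max + 1)
    mass = p ** (n - 1) * (1 - p)
    return SizeDistribution(mass, tail_mass=float(p**n_max))


def uniform_mixture_model(n_max: int = DEFAULT_N_MAX) -> SizeDistribution:
    """Occupancy uniform on [0,1] across cells: P(N=n) = 1 / (n (n+1)).

    The telescoping tail beyond ``n_max`` is exactly ``1 / (n_max + 1)``.
    """
    n = np.arange(1, n_max + 1)
    mass = 1.0 / (n * (n + 1.0))
    return SizeDistribution(mass, tail_mass=1.0 / (n_max + 1.0))


def uniform_p_grid(n_points: int = 1001) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint discretization of the uniform density on [0, 1].

    Returns ``(values, weights)`` with the ``n_points`` cell midpoints and
    equal weights.  Midpoints (rather than an endpoint-inclusive grid) make
    the equal-weight sum a midpoint quadrature rule, whose O(h^2) error
    keeps the discrete mixture within ~1e-7 of the exact 1/(n(n+1)) law at
    the default resolution.
    """
    if n_points < 1:
        raise ValidationError("n_points must be >= 1")
    values = (np.arange(n_points) + 0.5) / n_points
    weights = np.full(n_points, 1.0 / n_points)
    return values, weights


def mixture_model(
    p_values: np.ndarray,
    weights: np.ndarray,
    n_max: int = DEFAULT_N_MAX,
    *,
    weight_tol: float = 1e-9,
) -> SizeDistribution:
    """Pooled size distribution when occupancy p varies across cells.

    P(N=n) = sum_k w_k p_k^(n-1) (1-p_k).  Weights must sum to one; p
    values may include 1 (a p=1 cell contributes only tail mass — its
    granules are effectively infinite)."""
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values and weights must be equal-length 1-D arrays")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("mixture p values must lie in [0, 1]")
    if np.any(w < 0):
        raise ValidationError("mixture weights must be non-negative")
    if abs(float(w.sum()) - 1.0) > weight_tol:
        raise ValidationError(f"mixture weights sum to {w.sum():.12g}, not 1")
    n = np.arange(1, n_max + 1)
    mass = (w[:, None] * p[:, None] ** (n - 1) * (1 - p[:, None])).sum(axis=0)
    tail = float(np.sum(w * p**n_max))
    return SizeDistribution(mass, tail_mass=tail)


def segment_run_model(L: int, p: float) -> SizeDistribution:
    """WPB proportions from a Golgi made of independent L-mini-stack segments.

    The expected number of occupied runs of length ``k`` in one Bernoulli(p)
    segment of ``L`` sites is::

        E[k] = p^k (1-p) [ (L-k-1)(1-p) + 2 ]   for k < L
        E[L] = p^L

    (interior starts need an empty site on both flanks, the two boundary
    starts only one).  The model reports the proportions E[k] / sum_j E[j];
    at L = 3 and L = 4 these reduce to the classic trimer/tetramer run
    polynomials.
    """
    if L < 1:
        raise ValidationError("segment length L must be >= 1")
    if p == 0:
        raise DegenerateParameterError("p=0: segments generate no WPBs")
    _check_p(p, open_left=True, open_right=False)
    k = np.arange(1, L + 1, dtype=float)
    expected = p**k * (1 - p) * ((L - k - 1) * (1 - p) + 2.0)
    expected[-1] = p**L
    total = expected.sum()
    return SizeDistribution(expected / total, tail_mass=0.0)


def dimers_plus_ribbon_model(
    p: float, q: float, n_max: int = DEFAULT_N_MAX
) -> SizeDistribution:
    """Free mini-stack dimers (fraction q of mini-stacks) plus a long ribbon.

    With denominator D = (1-p) + q p / 2::

        P(N=1) = (1-p) [1 - p (1-q)] / D
        P(N=2) = p [ (1-p)^2 (1-q) + q/2 ] / D
        P(N=n) = (1-q) p^(n-1) (1-p)^2 / D      for n >= 3

    The numerators sum to D analytically, so normalization is exact.
    """
    if p in (0.0, 1.0):
        raise DegenerateParameterError("p must lie strictly inside (0, 1)")
    _check_p(p, open_left=True)
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"dimer proportion q={q} outside [0, 1]")
    if n_max < 2:
        raise ValidationError("n_max must be >= 2 for the three-branch formula")
    denom = (1 - p) + q * p / 2.0
    n = np.arange(1, n_max + 1)
    mass = (1 - q) * p ** (n - 1) * (1 - p) ** 2 / denom
    mass[0] = (1 - p) * (1 - p * (1 - q)) / denom
    mass[1] = p * ((1 - p) ** 2 * (1 - q) + q / 2.0) / denom
    # geometric tail of the ribbon branch beyond n_max
    tail = (1 - q) * (1 - p) * p**n_max / denom
    return SizeDistribution(mass, tail_mass=float(tail))


def instability_model(
    p: float, alpha: float, n_max: int = DEFAULT_N_MAX
) -> SizeDistribution:
    """Linear ribbon with selectively unstable 1Q-WPBs.

    ``alpha`` scales the steady-state abundance of 1Q-WPBs relative to the
    longer classes (alpha < 1: preferential loss, e.g. by basal exocytosis)::

        P(N=1)      = alpha (1-p) / [alpha (1-p) + p]
        P(N=n>=2)   = p^(n-1) (1-p) / [alpha (1-p) + p]

    ``alpha = 1`` recovers the plain geometric model.  Values above 1 are
    accepted (they arise when inverting the 1Q frequency of data outside
    the instability regime) but flagged by the fitting layer.
    """
    if p in (0.0, 1.0):
        raise DegenerateParameterError("p must lie strictly inside (0, 1)")
    _check_p(p, open_left=True)
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    denom = alpha * (1 - p) + p
    n = np.arange(1, n_max + 1)
    mass = p ** (n - 1) * (1 - p) / denom
    mass[0] = alpha * (1 - p) / denom
    tail = p**n_max / denom
    return SizeDistribution(mass, tail_mass=float(tail))


def alpha_from_f1(p: float, f1: float) -> float:
    """Invert the instability model at n = 1.

    Given the tail-fitted occupancy ``p`` and the observed 1Q-WPB frequency
    ``f1``, the alpha that reproduces ``f1`` exactly is::

        alpha = p f1 / [ (1-p) (1-f1) ]

    Returns alpha > 1 (flaggable by callers) when the observed 1Q class is
    *over*-represented relative to the geometric prediction.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("p must lie strictly inside (0, 1)")
    if not 0.0 < f1 < 1.0:
        raise ValidationError("f1 must lie strictly inside (0, 1)")
    return p * f1 / ((1 - p) * (1 - f1))
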