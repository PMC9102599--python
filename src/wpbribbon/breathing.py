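"""The "breathing" Golgi ribbon: stochastic mini-stack linking/unlinking.

Mini-stacks bind laterally at a size-independent rate ``r``; lateral bonds
break at rate ``d1`` if the split does not separate a stable dimer, and at
the slower rate ``d2`` if it does.  Two neighboring monomers always fuse
instantly into a dimer, so within a piece dimers are separated by at most
one monomer; pieces longer than five mini-stacks are ignored to keep the
system finite.  That leaves seven species::

    MONO      m           single mini-stack
    DIM       (mm)        stable dimer (internal bond breaks at d2)
    TRI       (mm)-m      dimer + end monomer
    TET_DD    (mm)-(mm)   two coupled dimers
    TET_MDM   m-(mm)-m    dimer flanked by two monomers
    PENT_END  m-(mm)-(mm) two dimers, monomer on the end
    PENT_MID  (mm)-m-(mm) two dimers, monomer in the middle

The two tetramer and two pentamer isomers must be tracked separately: they
carry different bond inventories and therefore different unbinding fluxes,
although an observed fragment length cannot distinguish them
(:func:`length_frequencies` pools them).

The exact stochastic dynamics is simulated with Gillespie's direct method
(:func:`ssa_simulate`, numba-accelerated when available); the mean-field
mass-action ODEs are generated mechanically from the same channel list
(:func:`meanfield_odes`, :func:`steady_state`).  Only the dimensionless
groups ``r*M/d1`` and ``d1/d2`` affect the steady-state length
frequencies, so fits fix ``r`` and ``M`` and search ``(d1, d2)``
(:func:`fit_rates`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .distributions import SizeDistribution
from .errors import ConvergenceError, ValidationError

__all__ = [
    "SPECIES",
    "SPECIES_LENGTH",
    "Channel",
    "ReactionState",
    "RateParams",
    "reaction_network",
    "ssa_simulate",
    "meanfield_odes",
    "steady_state",
    "length_frequencies",
    "fit_rates",
]

SPECIES = ("MONO", "DIM", "TRI", "TET_DD", "TET_MDM", "PENT_END", "PENT_MID")
#: mini-stacks per piece of each species (the conserved weight vector)
SPECIES_LENGTH = np.array([1, 2, 3, 4, 4, 5, 5], dtype=np.int64)
N_SPECIES = 7
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: defaults used throughout (population-scale simulation, dimensionless)
DEFAULT_R = 0.001
DEFAULT_M = 100_000
DEFAULT_T_END = 5000.0


class Channel(NamedTuple):
    """One reaction channel of the linking/unlinking network."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: str  # "r", "d1" or "d2"
    multiplier: float  # stoichiometric/statistical factor on the rate constant

    def stoichiometry(self) -> np.ndarray:
        nu = np.zeros(N_SPECIES, dtype=np.int64)
        for s in self.reactants:
            nu[_IDX[s]] -= 1
        for s in self.products:
            nu[_IDX[s]] += 1
        return nu


def reaction_network(dimer_split_in_pieces: bool = True) -> list[Channel]:
    """The canonical channel set.

    Binding channels all share the rate constant ``r`` (size-independent
    joining); attachments that could produce either of two isomers split
    1/2 : 1/2 (no end preference).  Unbinding has one channel per bond:
    weak bonds at ``d1``, internal dimer bonds at ``d2``; adjacent
    monomers exposed by a split fuse instantly, which is already folded
    into the products.  ``dimer_split_in_pieces=False`` disables the
    ``d2`` channels inside pieces larger than a free dimer (the
    alternative reading in which only isolated dimers can split).
    """
    bind = [
        Channel(("MONO", "MONO"), ("DIM",), "r", 1.0),
        Channel(("MONO", "DIM"), ("TRI",), "r", 1.0),
        Channel(("MONO", "TRI"), ("TET_DD",), "r", 0.5),
        Channel(("MONO", "TRI"), ("TET_MDM",), "r", 0.5),
        Channel(("DIM", "DIM"), ("TET_DD",), "r", 1.0),
        Channel(("MONO", "TET_DD"), ("PENT_END",), "r", 1.0),
        Channel(("MONO", "TET_MDM"), ("PENT_END",), "r", 1.0),
        Channel(("DIM", "TRI"), ("PENT_END",), "r", 0.5),
        Channel(("DIM", "TRI"), ("PENT_MID",), "r", 0.5),
    ]
    unbind_d1 = [
        Channel(("TRI",), ("MONO", "DIM"), "d1", 1.0),
        Channel(("TET_DD",), ("DIM", "DIM"), "d1", 1.0),
        Channel(("TET_MDM",), ("MONO", "TRI"), "d1", 2.0),
        Channel(("PENT_END",), ("DIM", "TRI"), "d1", 1.0),
        Channel(("PENT_END",), ("MONO", "TET_DD"), "d1", 1.0),
        Channel(("PENT_MID",), ("DIM", "TRI"), "d1", 2.0),
    ]
    unbind_d2 = [Channel(("DIM",), ("MONO", "MONO"), "d2", 1.0)]
    if dimer_split_in_pieces:
        unbind_d2 += [
            Channel(("TRI",), ("MONO", "DIM"), "d2", 1.0),
            Channel(("TET_DD",), ("MONO", "TRI"), "d2", 2.0),
            Channel(("TET_MDM",), ("DIM", "DIM"), "d2", 1.0),
            Channel(("PENT_END",), ("MONO", "TET_MDM"), "d2", 1.0),
            Channel(("PENT_END",), ("DIM", "TRI"), "d2", 1.0),
            Channel(("PENT_MID",), ("MONO", "TET_DD"), "d2", 2.0),
        ]
    return bind + unbind_d1 + unbind_d2


@dataclass(frozen=True)
class RateParams:
    """Kinetic parameters (all dimensionless)."""

    r: float = DEFAULT_R
    d1: float = 100.0
    d2: float = 10.0
    M: int = DEFAULT_M

    def __post_init__(self) -> None:
        if min(self.r, self.d1, self.d2) < 0:
            raise ValidationError("rates r, d1, d2 must be non-negative")
        if self.M <= 0:
            raise ValidationError("total mini-stack count M must be positive")

    @property
    def regime_flag(self) -> bool:
        """True in the physically expected regime d2 < d1 (dimer bonds
        more stable than weak bonds)."""
        return self.d2 < self.d1

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.d1, self.d2], dtype=float)


@dataclass
class ReactionState:
    """Species counts at a time point."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_SPECIES,):
            raise ValidationError(f"counts must have shape ({N_SPECIES},)")
        if np.any(c < 0):
            raise ValidationError("species counts must be non-negative")
        self.counts = c

    @property
    def ministacks(self) -> int:
        """Total mini-stacks, the conserved quantity sum_s len(s)*x_s."""
        return int(np.dot(SPECIES_LENGTH, self.counts))

    @property
    def pieces(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, species: str) -> int:
        return int(self.counts[_IDX[species]])

    @classmethod
    def all_monomers(cls, M: int) -> "ReactionState":
        c = np.zeros(N_SPECIES, dtype=np.int64)
        c[0] = M
        return cls(c)

    @classmethod
    def all_dimers(cls, M: int) -> "ReactionState":
        """M//2 dimers (plus one monomer if M is odd)."""
        c = np.zeros(N_SPECIES, dtype=np.int64)
        c[1] = M // 2
        c[0] = M % 2
        return cls(c)


# ---------------------------------------------------------------------------
# SSA core.  The channel list is compiled into flat arrays:
#   kind 0: unary           a = k * x_i
#   kind 1: pair, distinct  a = k * x_i * x_j
#   kind 2: pair, identical a = k * x_i * (x_i - 1) / 2
# with k = multiplier * {r, d1, d2}[rate_idx].
# ---------------------------------------------------------------------------


def _compile_network(channels: Sequence[Channel]):
    rate_map = {"r": 0, "d1": 1, "d2": 2}
    n = len(channels)
    kind = np.zeros(n, dtype=np.int64)
    ri = np.zeros(n, dtype=np.int64)
    rj = np.zeros(n, dtype=np.int64)
    rate_idx = np.zeros(n, dtype=np.int64)
    mult = np.zeros(n, dtype=np.float64)
    stoich = np.zeros((n, N_SPECIES), dtype=np.int64)
    for c, ch in enumerate(channels):
        rate_idx[c] = rate_map[ch.rate]
        mult[c] = ch.multiplier
        stoich[c] = ch.stoichiometry()
        if len(ch.reactants) == 1:
            kind[c], ri[c], rj[c] = 0, _IDX[ch.reactants[0]], -1
        elif ch.reactants[0] == ch.reactants[1]:
            kind[c], ri[c], rj[c] = 2, _IDX[ch.reactants[0]], -1
        else:
            kind[c], ri[c], rj[c] = 1, _IDX[ch.reactants[0]], _IDX[ch.reactants[1]]
    return kind, ri, rj, rate_idx, mult, stoich


def _ssa_loop(x, kind, ri, rj, rate_idx, mult, stoich, rates, t0, t_end,
              max_events, seed):
    """Gillespie direct method from t0 to t_end; mutates x in place.
    Returns (t, n_events)."""
    np.random.seed(seed)
    n_channels = kind.shape[0]
    a = np.empty(n_channels, dtype=np.float64)
    k_const = np.empty(n_channels, dtype=np.float64)
    for c in range(n_channels):
        k_const[c] = mult[c] * rates[rate_idx[c]]
    t = t0
    n_events = 0
    while t < t_end:
        a0 = 0.0
        for c in range(n_channels):
            k = k_const[c]
            xi = x[ri[c]]
            if kind[c] == 0:
                ac = k * xi
            elif kind[c] == 1:
                ac = k * xi * x[rj[c]]
            else:
                ac = k * xi * (xi - 1) * 0.5
            a[c] = ac
            a0 += ac
        if a0 <= 0.0:
            return t_end, n_events  # absorbing state
        t += -math.log(np.random.random()) / a0
        if t >= t_end:
            break
        u = np.random.random() * a0
        acc = 0.0
        chosen = n_channels - 1
        for c in range(n_channels):
            acc += a[c]
            if u < acc:
                chosen = c
                break
        for s in range(N_SPECIES):
            x[s] += stoich[chosen, s]
        n_events += 1
        if n_events >= max_events:
            raise RuntimeError("SSA exceeded max_events before t_end")
    return t_end, n_events


def _ssa_loop_fast(x, k, t0, t_end, max_events, seed):
    """Specialized Gillespie loop for the 22-slot channel layout of
    :func:`reaction_network` (slot order = list order with the toggle on;
    disabled channels carry k = 0).  Semantically identical to
    :func:`_ssa_loop`, written with scalar state for speed."""
    np.random.seed(seed)
    x0, x1, x2, x3, x4, x5, x6 = x[0], x[1], x[2], x[3], x[4], x[5], x[6]
    t = t0
    n_events = 0
    while t < t_end:
        a0 = k[0] * x0 * (x0 - 1) * 0.5   # M+M -> D
        a1 = k[1] * x0 * x1               # M+D -> T
        a2 = k[2] * x0 * x2               # M+T -> TDD
        a3 = k[3] * x0 * x2               # M+T -> TMDM
        a4 = k[4] * x1 * (x1 - 1) * 0.5   # D+D -> TDD
        a5 = k[5] * x0 * x3               # M+TDD -> PE
        a6 = k[6] * x0 * x4               # M+TMDM -> PE
        a7 = k[7] * x1 * x2               # D+T -> PE
        a8 = k[8] * x1 * x2               # D+T -> PM
        a9 = k[9] * x2                    # T -> M+D       (d1)
        a10 = k[10] * x3                  # TDD -> 2D      (d1)
        a11 = k[11] * x4                  # TMDM -> M+T    (2 d1)
        a12 = k[12] * x5                  # PE -> D+T      (d1)
        a13 = k[13] * x5                  # PE -> M+TDD    (d1)
        a14 = k[14] * x6                  # PM -> D+T      (2 d1)
        a15 = k[15] * x1                  # D -> 2M        (d2)
        a16 = k[16] * x2                  # T -> M+D       (d2)
        a17 = k[17] * x3                  # TDD -> M+T     (2 d2)
        a18 = k[18] * x4                  # TMDM -> 2D     (d2)
        a19 = k[19] * x5                  # PE -> M+TMDM   (d2)
        a20 = k[20] * x5                  # PE -> D+T      (d2)
        a21 = k[21] * x6                  # PM -> M+TDD    (2 d2)
        asum = (a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9 + a10 + a11
                + a12 + a13 + a14 + a15 + a16 + a17 + a18 + a19 + a20 + a21)
        if asum <= 0.0:
            break
        t += -math.log(np.random.random()) / asum
        if t >= t_end:
            break
        s1 = a0 + a1
        s2 = s1 + a2
        s3 = s2 + a3
        s4 = s3 + a4
        s5 = s4 + a5
        s6 = s5 + a6
        s7 = s6 + a7
        s8 = s7 + a8
        s9 = s8 + a9
        s10 = s9 + a10
        s11 = s10 + a11
        s12 = s11 + a12
        s13 = s12 + a13
        s14 = s13 + a14
        s15 = s14 + a15
        s16 = s15 + a16
        s17 = s16 + a17
        s18 = s17 + a18
        s19 = s18 + a19
        s20 = s19 + a20
        u = np.random.random() * asum
        if u < a0:
            x0 -= 2; x1 += 1
        elif u < s1:
            x0 -= 1; x1 -= 1; x2 += 1
        elif u < s2:
            x0 -= 1; x2 -= 1; x3 += 1
        elif u < s3:
            x0 -= 1; x2 -= 1; x4 += 1
        elif u < s4:
            x1 -= 2; x3 += 1
        elif u < s5:
            x0 -= 1; x3 -= 1; x5 += 1
        elif u < s6:
            x0 -= 1; x4 -= 1; x5 += 1
        elif u < s7:
            x1 -= 1; x2 -= 1; x5 += 1
        elif u < s8:
            x1 -= 1; x2 -= 1; x6 += 1
        elif u < s9:
            x2 -= 1; x0 += 1; x1 += 1
        elif u < s10:
            x3 -= 1; x1 += 2
        elif u < s11:
            x4 -= 1; x0 += 1; x2 += 1
        elif u < s12:
            x5 -= 1; x1 += 1; x2 += 1
        elif u < s13:
            x5 -= 1; x0 += 1; x3 += 1
        elif u < s14:
            x6 -= 1; x1 += 1; x2 += 1
        elif u < s15:
            x1 -= 1; x0 += 2
        elif u < s16:
            x2 -= 1; x0 += 1; x1 += 1
        elif u < s17:
            x3 -= 1; x0 += 1; x2 += 1
        elif u < s18:
            x4 -= 1; x1 += 2
        elif u < s19:
            x5 -= 1; x0 += 1; x4 += 1
        elif u < s20:
            x5 -= 1; x1 += 1; x2 += 1
        else:
            x6 -= 1; x0 += 1; x3 += 1
        n_events += 1
        if n_events >= max_events:
            raise RuntimeError("SSA exceeded max_events before t_end")
    x[0], x[1], x[2], x[3], x[4], x[5], x[6] = x0, x1, x2, x3, x4, x5, x6
    return t_end, n_events


def _fast_k(channels: Sequence[Channel], rates: "RateParams") -> np.ndarray:
    """Per-slot rate constants for :func:`_ssa_loop_fast`; channel list
    order matches the slot layout (disabled channels are simply absent and
    leave zeros)."""
    rate_map = {"r": rates.r, "d1": rates.d1, "d2": rates.d2}
    k = np.zeros(22, dtype=np.float64)
    for slot, ch in enumerate(channels):
        k[slot] = ch.multiplier * rate_map[ch.rate]
    return k


try:  # optional acceleration; the pure-python loops are the reference
    from numba import njit

    _ssa_loop_fast_jit = njit(cache=True, fastmath=True)(_ssa_loop_fast)
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def ssa_simulate(
    init: ReactionState,
    rates: RateParams,
    t_end: float = DEFAULT_T_END,
    seed: int | None = None,
    *,
    sample_times: Sequence[float] | None = None,
    dimer_split_in_pieces: bool = True,
    max_events: int = 4_000_000_000,
) -> ReactionState | list[ReactionState]:
    """Exact Gillespie realization of the linking/unlinking network.

    Returns the state at ``t_end``, or — if ``sample_times`` is given — a
    list of state snapshots at those times (final time included only if
    listed).  Mini-stack conservation holds exactly at every event because
    every channel's stoichiometry conserves the length-weighted count.
    """
    if init.ministacks != rates.M:
        raise ValidationError(
            f"initial state holds {init.ministacks} mini-stacks, rates.M={rates.M}"
        )
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    if seed is None:
        raise ValidationError("an explicit seed is required for reproducibility")
    channels = reaction_network(dimer_split_in_pieces)
    x = init.counts.copy()
    times = sorted(sample_times) if sample_times is not None else [t_end]
    if times[-1] > t_end or times[0] <= 0:
        raise ValidationError("sample_times must lie in (0, t_end]")
    snapshots: list[ReactionState] = []
    t = 0.0
    for i, t_stop in enumerate(times):
        # an independent substream per segment keeps the draw sequence
        # well-defined regardless of how many events each segment takes
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        t, _ = _run_segment(x, channels, rates, t, float(t_stop), max_events,
                            sub_seed)
        snapshots.append(ReactionState(x.copy(), time=float(t_stop)))
    return snapshots if sample_times is not None else snapshots[-1]


def _run_segment(x, channels, rates, t0, t_stop, max_events, sub_seed):
    """Dispatch one SSA segment to the specialized kernel (numba) or the
    generic reference loop."""
    if _HAVE_NUMBA:
        return _ssa_loop_fast_jit(
            x, _fast_k(channels, rates), t0, t_stop, max_events, sub_seed
        )
    kind, ri, rj, rate_idx, mult, stoich = _compile_network(channels)
    return _ssa_loop(
        x, kind, ri, rj, rate_idx, mult, stoich, rates.as_array(), t0, t_stop,
        max_events, sub_seed,
    )


def ssa_event_count(
    init: ReactionState,
    rates: RateParams,
    t_end: float,
    seed: int,
    dimer_split_in_pieces: bool = True,
) -> tuple[ReactionState, int]:
    """As :func:`ssa_simulate` (single segment) but also reports the number
    of reaction events fired."""
    if init.ministacks != rates.M:
        raise ValidationError("initial state inconsistent with rates.M")
    channels = reaction_network(dimer_split_in_pieces)
    x = init.counts.copy()
    sub_seed = int(np.random.SeedSequence([seed, 0]).generate_state(1)[0])
    _, n_events = _run_segment(
        x, channels, rates, 0.0, float(t_end), 4_000_000_000, sub_seed
    )
    return ReactionState(x, time=float(t_end)), n_events


# ---------------------------------------------------------------------------
# Mean-field ODEs
# ---------------------------------------------------------------------------


def meanfield_odes(rates: RateParams, dimer_split_in_pieces: bool = True):
    """Mass-action ODE right-hand side dx/dt = f(t, x), generated
    mechanically from :func:`reaction_network` (identical-pair propensity
    x^2/2 in the mean-field limit)."""
    channels = reaction_network(dimer_split_in_pieces)
    kind, ri, rj, rate_idx, mult, stoich = _compile_network(channels)
    rate_arr = rates.as_array()
    k_const = mult * rate_arr[rate_idx]
    stoich_f = stoich.astype(float)

    def rhs(t, x):
        a = np.empty(len(kind))
        for c in range(len(kind)):
            if kind[c] == 0:
                a[c] = k_const[c] * x[ri[c]]
            elif kind[c] == 1:
                a[c] = k_const[c] * x[ri[c]] * x[rj[c]]
            else:
                a[c] = k_const[c] * x[ri[c]] ** 2 * 0.5
        return stoich_f.T @ a

    return rhs


def steady_state(
    rates: RateParams,
    init: ReactionState | None = None,
    t_end: float = DEFAULT_T_END,
    *,
    dimer_split_in_pieces: bool = True,
    residual_tol: float = 1e-8,
) -> tuple[np.ndarray, ReactionState]:
    """Mean-field steady state: stiff integration to ``t_end`` plus a
    residual check ||dx/dt||_inf < residual_tol * M.

    Returns ``(length_frequencies, mean state)``; the state carries the
    (real-valued, rounded) species means.
    """
    if init is None:
        init = ReactionState.all_monomers(rates.M)
    elif init.ministacks != rates.M:
        raise ValidationError("initial state inconsistent with rates.M")
    rhs = meanfield_odes(rates, dimer_split_in_pieces)
    sol = solve_ivp(
        rhs, (0.0, t_end), init.counts.astype(float),
        method="LSODA", rtol=1e-10, atol=1e-10 * rates.M,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}")
    x = sol.y[:, -1]
    residual = float(np.max(np.abs(rhs(t_end, x))))
    if residual >= residual_tol * rates.M:
        raise ConvergenceError(
            f"mean-field residual {residual:.3e} above tolerance", residual=residual
        )
    freqs = _freqs_from_counts(x)
    return freqs, ReactionState(np.maximum(np.rint(x), 0).astype(np.int64), t_end)


# ---------------------------------------------------------------------------
# Observables and fitting
# ---------------------------------------------------------------------------


def _freqs_from_counts(x: np.ndarray) -> np.ndarray:
    total = float(np.sum(x))
    if total <= 0:
        raise ValidationError("no Golgi pieces present")
    by_len = np.array([x[0], x[1], x[2], x[3] + x[4], x[5] + x[6]], dtype=float)
    return by_len / total


def length_frequencies(state: ReactionState) -> SizeDistribution:
    """Relative frequencies of Golgi pieces of length 1..5 mini-stacks.

    The two tetramer and the two pentamer isomers are pooled: a measured
    fragment length cannot distinguish their internal arrangement.
    """
    freqs = _freqs_from_counts(state.counts.astype(float))
    total = state.pieces
    return SizeDistribution(freqs, tail_mass=0.0, total_count=total)


def fit_rates(
    observed: SizeDistribution,
    d1_grid: Sequence[float],
    d2_grid: Sequence[float],
    *,
    r: float = DEFAULT_R,
    M: int = DEFAULT_M,
    t_end: float = DEFAULT_T_END,
    seed: int | None = None,
    init: ReactionState | None = None,
    dimer_split_in_pieces: bool = True,
):
    """Grid-search (d1, d2) minimizing the KS distance between simulated
    and observed Golgi fragment-length frequencies.

    For each grid pair one SSA run (fixed ``r`` and ``M``; only r*M/d1 and
    d1/d2 matter at steady state) is taken to ``t_end`` and its pooled
    length frequencies compared with ``observed``.  Ties break toward
    smaller d2, then smaller d1.  A best fit on the edge of either grid is
    flagged — it would call for a broader search.

    Returns a :class:`~wpbribbon.fitting.FitResult`.
    """
    from .fitting import FitResult, ks_distance  # local import avoids a cycle

    observed.require_normalized()
    if observed.n_max != 5:
        observed = observed.lumped(5) if observed.n_max > 5 else observed.extended(5)
    d1_grid = sorted(float(v) for v in d1_grid)
    d2_grid = sorted(float(v) for v in d2_grid)
    if not d1_grid or not d2_grid:
        raise ValidationError("d1 and d2 grids must be non-empty")
    if seed is None:
        raise ValidationError("an explicit seed is required")
    if init is None:
        init = ReactionState.all_monomers(M)
    ss = np.random.SeedSequence(seed)
    best = None
    results = []
    i = 0
    for d2 in d2_grid:  # d2-major ascending order: first minimum wins ties
        for d1 in d1_grid:
            run_seed = int(ss.spawn(1)[0].generate_state(1)[0])
            i += 1
            rates = RateParams(r=r, d1=d1, d2=d2, M=M)
            final = ssa_simulate(
                init, rates, t_end=t_end, seed=run_seed,
                dimer_split_in_pieces=dimer_split_in_pieces,
            )
            ks = ks_distance(length_frequencies(final), observed)
            results.append((d1, d2, ks))
            if best is None or ks < best[2]:
                best = (d1, d2, ks)
    d1_best, d2_best, ks_best = best
    warnings = []
    if d1_best in (d1_grid[0], d1_grid[-1]) and len(d1_grid) > 1:
        warnings.append(f"best d1={d1_best} on the grid boundary; widen the search")
    if d2_best in (d2_grid[0], d2_grid[-1]) and len(d2_grid) > 1:
        warnings.append(f"best d2={d2_best} on the grid boundary; widen the search")
    return FitResult(
        family="breathing-ribbon",
        params={"d1": d1_best, "d2": d2_best, "r": r, "M": M},
        ks_distance=ks_best,
        grid={
            "d1": d1_grid,
            "d2": d2_grid,
            "t_end": t_end,
            "seed": seed,
            "scan": results,
        },
        warnings=warnings,
    )
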