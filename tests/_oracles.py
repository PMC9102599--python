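"""Independent oracles used by the test suite.

These deliberately avoid the library's own closed forms: run proportions by
exhaustive enumeration of occupancy patterns, mixture masses by adaptive
quadrature, the dimers-plus-ribbon distribution by direct Monte-Carlo
simulation of a lattice, and the linking/unlinking channel set by symbolic
enumeration of bond layouts.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.integrate import quad


# ---------------------------------------------------------------------------
# Run-length enumeration on a finite Bernoulli segment
# ---------------------------------------------------------------------------


def segment_run_proportions(L: int, p: float) -> np.ndarray:
    """Expected proportions of occupied runs of length 1..L in a segment of
    L sites occupied i.i.d. with probability p, by summing over all 2^L
    occupancy patterns."""
    expected = np.zeros(L)
    for pattern in itertools.product((0, 1), repeat=L):
        ones = sum(pattern)
        prob = p**ones * (1 - p) ** (L - ones)
        run = 0
        for site in pattern + (0,):
            if site:
                run += 1
            elif run:
                expected[run - 1] += prob
                run = 0
    total = expected.sum()
    return expected / total


# ---------------------------------------------------------------------------
# Uniform-occupancy mixture by quadrature
# ---------------------------------------------------------------------------


def uniform_mixture_mass(n: int) -> float:
    """integral_0^1 p^(n-1) (1-p) dp by adaptive quadrature."""
    val, _ = quad(lambda p: p ** (n - 1) * (1 - p), 0.0, 1.0, epsabs=1e-12)
    return val


# ---------------------------------------------------------------------------
# Monte-Carlo lattice oracle for the free-dimers-plus-ribbon model
# ---------------------------------------------------------------------------


def simulate_dimers_plus_ribbon(
    p: float, q: float, n_ministacks: int, seed: int, n_max: int = 30
) -> np.ndarray:
    """WPB size-class frequencies from direct simulation: a fraction q of
    mini-stacks paired into free dimers, the rest one long (circular)
    ribbon, every mini-stack occupied i.i.d. with probability p.  Runs of
    occupied neighbors become WPBs.  Returns masses for classes 1..n_max."""
    rng = np.random.default_rng(seed)
    n_dimers = int(round(q * n_ministacks / 2))
    n_ribbon = n_ministacks - 2 * n_dimers
    counts = np.zeros(n_max, dtype=np.int64)
    # free dimers: 2 occupied -> one 2Q-WPB; 1 occupied -> one 1Q-WPB
    occ = rng.random((n_dimers, 2)) < p
    n_occ = occ.sum(axis=1)
    counts[0] += int((n_occ == 1).sum())
    counts[1] += int((n_occ == 2).sum())
    # circular ribbon: count runs of consecutive occupied sites
    sites = rng.random(n_ribbon) < p
    if sites.all():
        counts[min(n_ribbon, n_max) - 1] += 1
    else:
        shift = int(np.argmin(sites))  # rotate so position 0 is empty
        sites = np.roll(sites, -shift)
        padded = np.concatenate([sites.astype(np.int8), [0]])
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for ln in ends - starts:
            counts[min(int(ln), n_max) - 1] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Bond-layout enumeration of the linking/unlinking reaction scheme
# ---------------------------------------------------------------------------

# a piece is its sequence of bonds: 'S' = internal dimer bond, 'W' = weak
LAYOUTS = {
    "": "MONO",
    "S": "DIM",
    "SW": "TRI",
    "SWS": "TET_DD",
    "WSW": "TET_MDM",
    "SWSW": "PENT_END",
    "SWWS": "PENT_MID",
}


def _canon(bonds: str) -> str:
    return min(bonds, bonds[::-1])


def _classify(bonds: str) -> str:
    return LAYOUTS[_canon(bonds)]


def _fuse(bonds: str) -> str:
    """Two adjacent free monomers always fuse: turn any W bond joining two
    monomers that are not part of an S pair into an S bond."""
    b = list(bonds)
    changed = True
    while changed:
        changed = False
        for i, bond in enumerate(b):
            if bond != "W":
                continue
            left_free = i == 0 or b[i - 1] != "S"
            right_free = i == len(b) - 1 or b[i + 1] != "S"
            if left_free and right_free:
                b[i] = "S"
                changed = True
    return "".join(b)


def enumerate_channels(dimer_split_in_pieces: bool = True) -> Counter:
    """All channels implied by the bond layouts, as a Counter keyed by
    (sorted reactants, sorted products, rate symbol) -> multiplier."""
    channels: Counter = Counter()
    # unbinding: one channel per bond
    for bonds, name in LAYOUTS.items():
        for j, bond in enumerate(bonds):
            rate = "d1" if bond == "W" else "d2"
            if bond == "S" and not dimer_split_in_pieces and name != "DIM":
                continue
            left, right = _fuse(bonds[:j]), _fuse(bonds[j + 1 :])
            products = tuple(sorted((_classify(left), _classify(right))))
            channels[((name,), products, rate)] += 1
    # binding: unordered species pairs, all end-to-end orientations
    sizes = {name: len(bonds) + 1 for bonds, name in LAYOUTS.items()}
    by_name = {name: bonds for bonds, name in LAYOUTS.items()}
    for a, b in itertools.combinations_with_replacement(sorted(sizes), 2):
        if sizes[a] + sizes[b] > 5:
            continue
        outcomes: Counter = Counter()
        for a_bonds in {by_name[a], by_name[a][::-1]}:
            for b_bonds in {by_name[b], by_name[b][::-1]}:
                joined = _fuse(a_bonds + "W" + b_bonds)
                outcomes[_classify(joined)] += 1
        # each orientation pair is equally likely; distinct strings collapse
        n_a = len({by_name[a], by_name[a][::-1]})
        n_b = len({by_name[b], by_name[b][::-1]})
        total = n_a * n_b
        for product, k in outcomes.items():
            channels[(tuple(sorted((a, b))), (product,), "r")] += k / total
    return channels
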