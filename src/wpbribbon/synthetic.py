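"""Synthetic WPB length tables and Golgi fragment observations.

Generators emulate the statistical structure of the high-throughput
morphometry data the analysis consumes: ~100,000 WPB lengths per condition,
quantized at l = 0.576 μm with Gaussian measurement noise; cell-to-cell
variability in occupancy (Beta-distributed p); multi-condition knockdown
series sharing a single 1Q-instability alpha; and multinomial Golgi
fragment-length tables.  Every generator is deterministic given its seed
and returns a ground-truth manifest so fits can be scored automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import SizeDistribution
from .errors import ValidationError
from .quantize import DEFAULT_QUANTUM_UM, LengthTable

__all__ = [
    "SyntheticSpec",
    "sample_wpb_lengths",
    "sample_cell_population",
    "knockdown_series",
    "sample_golgi_fragments",
    "recovery_report",
]

#: default measurement noise, μm — well below half a quantum (0.288 μm), so
#: quantization at the default scale is robust to it
DEFAULT_NOISE_SD = 0.05


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic WPB length table.

    family : "geometric" or "instability"
    params : model parameters (p; alpha for the instability family)
    cell_population : optional {"n_cells": int, "beta_a": float,
        "beta_b": float, "weighting": "density"|"equal"} — per-cell p drawn
        from Beta(a, b)
    """

    family: str = "instability"
    params: Mapping[str, float] = field(
        default_factory=lambda: {"p": 0.5692, "alpha": 0.2610}
    )
    n_wpbs: int = 100_000
    l_um: float = DEFAULT_QUANTUM_UM
    length_noise_sd: float = DEFAULT_NOISE_SD
    cell_population: Mapping | None = None
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wpbs <= 0:
            raise ValidationError("n_wpbs must be positive")
        if self.length_noise_sd < 0:
            raise ValidationError("length noise sd must be non-negative")
        if self.l_um <= 0:
            raise ValidationError("quantum length must be positive")
        if self.family not in ("geometric", "instability"):
            raise ValidationError(f"unknown model family {self.family!r}")
        if self.cell_population is not None:
            a = self.cell_population.get("beta_a", 1.0)
            b = self.cell_population.get("beta_b", 1.0)
            if a <= 0 or b <= 0:
                raise ValidationError("Beta parameters must be positive")


def _sample_geometric_classes(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if p == 0.0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 - p, size=n).astype(np.int64)


def _sample_instability_classes(
    p: float, alpha: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact sampler: 1Q with probability f1 = a(1-p)/(a(1-p)+p); the n>=2
    conditional is a shifted geometric, P(n | n>=2) = p^(n-2) (1-p)."""
    f1 = alpha * (1 - p) / (alpha * (1 - p) + p)
    is_one = rng.random(n) < f1
    out = np.ones(n, dtype=np.int64)
    k = int((~is_one).sum())
    out[~is_one] = 1 + rng.geometric(1.0 - p, size=k).astype(np.int64)
    return out


def _classes_to_lengths(
    classes: np.ndarray, l_um: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    lengths = classes.astype(float) * l_um
    if noise_sd > 0:
        lengths = lengths + rng.normal(0.0, noise_sd, size=lengths.size)
        bad = lengths <= 0
        while bad.any():  # truncate the noise at zero by redrawing
            lengths[bad] = classes[bad] * l_um + rng.normal(
                0.0, noise_sd, size=int(bad.sum())
            )
            bad = lengths <= 0
    return lengths


def _draw_classes(spec: SyntheticSpec, n: int, rng: np.random.Generator, p=None):
    p = spec.params["p"] if p is None else p
    if spec.family == "geometric":
        return _sample_geometric_classes(p, n, rng)
    alpha = spec.params.get("alpha", 1.0)
    if alpha == 1.0:
        return _sample_geometric_classes(p, n, rng)
    return _sample_instability_classes(p, alpha, n, rng)


def sample_wpb_lengths(spec: SyntheticSpec) -> tuple[LengthTable, dict]:
    """Draw a WPB length table from the specified ribbon model.

    Quanta counts are drawn exactly from the model; lengths are
    ``n * l_um`` plus zero-mean Gaussian noise truncated positive.  Returns
    the table and a ground-truth manifest (parameters, seed, counts).
    """
    if spec.cell_population is not None:
        return sample_cell_population(spec)
    rng = np.random.default_rng(spec.seed)
    classes = _draw_classes(spec, spec.n_wpbs, rng)
    lengths = _classes_to_lengths(classes, spec.l_um, spec.length_noise_sd, rng)
    table = LengthTable.from_records(lengths, condition=spec.condition)
    table.df["true_class"] = classes
    manifest = {
        "generator": "sample_wpb_lengths",
        "family": spec.family,
        "params": dict(spec.params),
        "n_wpbs": spec.n_wpbs,
        "l_um": spec.l_um,
        "length_noise_sd": spec.length_noise_sd,
        "condition": spec.condition,
        "seed": spec.seed,
    }
    return table, manifest


def sample_cell_population(spec: SyntheticSpec) -> tuple[LengthTable, dict]:
    """WPB table from a population of cells with Beta-distributed occupancy.

    Each cell draws p_i ~ Beta(a, b); its share of the ``n_wpbs`` total is
    proportional to the expected WPB density p_i (1 - p_i) under the
    infinite-ribbon model (``weighting="density"``, default) or equal
    (``weighting="equal"``).  Quanta are then geometric given p_i.
    """
    if spec.cell_population is None:
        raise ValidationError("spec.cell_population is required")
    cp = spec.cell_population
    n_cells = int(cp.get("n_cells", 1000))
    a, b = float(cp.get("beta_a", 1.0)), float(cp.get("beta_b", 1.0))
    weighting = cp.get("weighting", "density")
    if weighting not in ("density", "equal"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    if n_cells <= 0:
        raise ValidationError("n_cells must be positive")
    rng = np.random.default_rng(spec.seed)
    p_cells = rng.beta(a, b, size=n_cells)
    if weighting == "density":
        w = p_cells * (1 - p_cells)
        if w.sum() <= 0:
            raise ValidationError("degenerate cell weights (all p in {0,1})")
        w = w / w.sum()
    else:
        w = np.full(n_cells, 1.0 / n_cells)
    per_cell = rng.multinomial(spec.n_wpbs, w)
    frames = []
    for i, (p_i, n_i) in enumerate(zip(p_cells, per_cell)):
        if n_i == 0:
            continue
        classes = _sample_geometric_classes(float(p_i), int(n_i), rng)
        lengths = _classes_to_lengths(classes, spec.l_um, spec.length_noise_sd, rng)
        frames.append(
            pd.DataFrame(
                {
                    "length_um": lengths,
                    "condition": spec.condition,
                    "cell_id": f"cell_{i:05d}",
                    "true_class": classes,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["organelle_id"] = np.arange(len(df))
    table = LengthTable(df)
    manifest = {
        "generator": "sample_cell_population",
        "family": "geometric-beta-mixture",
        "beta_a": a,
        "beta_b": b,
        "n_cells": n_cells,
        "weighting": weighting,
        "p_cells": p_cells.tolist(),
        "n_wpbs": spec.n_wpbs,
        "l_um": spec.l_um,
        "length_noise_sd": spec.length_noise_sd,
        "seed": spec.seed,
    }
    return table, manifest


def knockdown_series(
    p_by_condition: Mapping[str, float],
    alpha: float,
    n_per_condition: int = 100_000,
    *,
    l_um: float = DEFAULT_QUANTUM_UM,
    length_noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[LengthTable, dict]:
    """Multi-condition series (e.g. a VWF siRNA titration) sharing one alpha.

    Each condition draws ``n_per_condition`` WPBs from the instability
    model at its own occupancy p_c and the common alpha — the recovery
    surface for the shared-alpha fitting pipeline.
    """
    if len(p_by_condition) < 2:
        raise ValidationError("a knockdown series needs >= 2 conditions")
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("shared alpha must lie in (0, 1]")
    root = np.random.SeedSequence(seed)
    frames = []
    for child, (cond, p_c) in zip(root.spawn(len(p_by_condition)),
                                  p_by_condition.items()):
        rng = np.random.default_rng(child)
        if not 0.0 < p_c < 1.0:
            raise ValidationError(f"condition {cond!r}: p={p_c} outside (0, 1)")
        classes = (
            _sample_geometric_classes(p_c, n_per_condition, rng)
            if alpha == 1.0
            else _sample_instability_classes(p_c, alpha, n_per_condition, rng)
        )
        lengths = _classes_to_lengths(classes, l_um, length_noise_sd, rng)
        frames.append(
            pd.DataFrame(
                {"length_um": lengths, "condition": cond, "true_class": classes}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["organelle_id"] = np.arange(len(df))
    table = LengthTable(df)
    manifest = {
        "generator": "knockdown_series",
        "family": "instability",
        "p_by_condition": dict(p_by_condition),
        "alpha": alpha,
        "n_per_condition": n_per_condition,
        "l_um": l_um,
        "length_noise_sd": length_noise_sd,
        "seed": seed,
    }
    return table, manifest


def sample_golgi_fragments(
    frequencies: SizeDistribution | Sequence[float],
    n_fragments: int,
    seed: int,
    *,
    l_um: float | None = None,
) -> pd.DataFrame:
    """Multinomial sample of Golgi fragment lengths (1..5 mini-stacks).

    ``frequencies`` may be a SizeDistribution over classes 1..5 (e.g. from
    :func:`wpbribbon.breathing.length_frequencies`) or a plain 5-vector.
    With ``l_um`` set, a ``length_um`` column is added (class * l_um) for
    end-to-end quantization tests.
    """
    if n_fragments <= 0:
        raise ValidationError("n_fragments must be positive")
    if isinstance(frequencies, SizeDistribution):
        frequencies.require_normalized()
        freqs = frequencies.extended(5).mass if frequencies.n_max < 5 else frequencies.mass
        if frequencies.n_max > 5:
            raise ValidationError("fragment frequencies must cover lengths 1..5 only")
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.size != 5 or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-6:
            raise ValidationError("frequencies must be 5 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fragments, freqs / freqs.sum())
    lengths = np.repeat(np.arange(1, 6), counts)
    rng.shuffle(lengths)
    df = pd.DataFrame({"fragment_id": np.arange(n_fragments), "length_class": lengths})
    if l_um is not None:
        df["length_um"] = df["length_class"] * float(l_um)
    return df


def recovery_report(fit_params: Mapping[str, float], manifest: Mapping) -> dict:
    """Compare fitted parameters against a generator manifest's truth."""
    truth = manifest.get("params", {k: manifest[k] for k in ("alpha",)
                                    if k in manifest})
    report = {}
    for name, fitted in fit_params.items():
        if name in truth:
            report[name] = {
                "true": float(truth[name]),
                "fitted": float(fitted),
                "abs_error": abs(float(fitted) - float(truth[name])),
            }
    return report
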