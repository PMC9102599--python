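"""Ingest organelle-length tables and quantize them into size classes.

WPB lengths measured by high-throughput morphometry (one row per organelle,
in μm) are converted to integer numbers of VWF quanta by dividing by the
quantum length ``l`` (median 0.576 μm in HUVECs) and rounding.  Two rounding
policies are provided: ``"nearest"`` (default; ties at exact half-multiples
round away from zero) and ``"ceil"``.  Sub-half-quantum objects are clamped
to class 1 by default — every segmented WPB contains at least one quantum —
or dropped on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .distributions import SizeDistribution
from .errors import EmptyInputError, ValidationError

__all__ = [
    "DEFAULT_QUANTUM_UM",
    "QuantumScale",
    "LengthTable",
    "load_length_table",
    "quantize_lengths",
    "empirical_distribution",
    "long_fraction",
]

#: median VWF quantum length in HUVECs, μm
DEFAULT_QUANTUM_UM = 0.576

#: canonical column names of a length table
COLUMNS = ["organelle_id", "length_um", "condition", "cell_id", "compartment"]

VALID_COMPARTMENTS = {"golgi", "cytoplasm", "unassigned"}


@dataclass(frozen=True)
class QuantumScale:
    """The quantum length used to express WPB sizes in size classes."""

    l_um: float = DEFAULT_QUANTUM_UM

    def __post_init__(self) -> None:
        if not self.l_um > 0:
            raise ValidationError("quantum length must be positive")


@dataclass
class LengthTable:
    """Validated per-organelle length records.

    ``df`` has columns ``organelle_id``, ``length_um`` (> 0, μm),
    ``condition`` (non-empty label), ``cell_id`` and ``compartment``
    (optional; missing as NA / "unassigned").  ``n_rejected`` counts input
    rows dropped for missing or non-positive lengths.
    """

    df: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("length_um", "condition") if c not in df.columns]
        if missing:
            raise ValidationError(f"length table missing columns: {missing}")
        if len(df) == 0:
            raise EmptyInputError("length table has no records")
        if not (df["length_um"] > 0).all():
            raise ValidationError("all length_um values must be positive")
        cond = df["condition"].astype(str)
        if (cond.str.len() == 0).any():
            raise ValidationError("condition labels must be non-empty")
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        self.df = df[COLUMNS + [c for c in df.columns if c not in COLUMNS]]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return self.df["length_um"].to_numpy(dtype=float)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].astype(str).unique())

    @classmethod
    def from_records(
        cls,
        lengths_um: Iterable[float],
        condition: str = "control",
        cell_id: Iterable | None = None,
        compartment: Iterable | str | None = None,
    ) -> "LengthTable":
        lengths = np.asarray(list(lengths_um), dtype=float)
        df = pd.DataFrame(
            {
                "organelle_id": np.arange(lengths.size),
                "length_um": lengths,
                "condition": condition,
            }
        )
        if cell_id is not None:
            df["cell_id"] = list(cell_id)
        if compartment is not None:
            df["compartment"] = (
                compartment if isinstance(compartment, str) else list(compartment)
            )
        return cls(df)


def load_length_table(
    path, dialect: Mapping[str, str] | None = None, *, sep: str | None = None
) -> LengthTable:
    """Read a delimited morphometry export into a :class:`LengthTable`.

    ``dialect`` maps canonical column names to the file's column names,
    e.g. ``{"length_um": "Length (um)", "condition": "treatment"}``.
    Rows with missing or non-positive lengths are rejected and counted in
    ``n_rejected``.  The delimiter is sniffed from the extension unless
    ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise OSError(f"cannot read length table {path!r}: {exc}") from exc
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    if "length_um" not in raw.columns:
        raise ValidationError(
            f"no 'length_um' column in {path!r}; map it via the dialect config"
        )
    lengths = pd.to_numeric(raw["length_um"], errors="coerce")
    ok = lengths.notna() & (lengths > 0)
    n_rejected = int((~ok).sum())
    kept = raw.loc[ok].copy()
    if len(kept) == 0:
        raise EmptyInputError(f"{path!r} contains no rows with a valid positive length")
    kept["length_um"] = lengths[ok]
    if "condition" not in kept.columns:
        kept["condition"] = "unlabeled"
    if "organelle_id" not in kept.columns:
        kept["organelle_id"] = np.arange(len(kept))
    return LengthTable(kept.reset_index(drop=True), n_rejected=n_rejected)


def _round_nearest_away(x: np.ndarray) -> np.ndarray:
    # half away from zero (x > 0 here), unlike numpy's banker's rounding
    return np.floor(x + 0.5)


def quantize_lengths(
    table: LengthTable,
    scale: QuantumScale | float = DEFAULT_QUANTUM_UM,
    policy: str = "nearest",
    *,
    subquantum: str = "clamp",
) -> LengthTable:
    """Attach a ``quanta_class`` column: organelle length in quantum units.

    policy : "nearest" (round to nearest integer, ties away from zero) or
        "ceil" (round up).
    subquantum : what to do with objects that would round to class 0 —
        "clamp" (to class 1, default) or "drop".
    """
    if isinstance(scale, (int, float)):
        scale = QuantumScale(float(scale))
    if policy not in ("nearest", "ceil"):
        raise ValidationError(f"unknown rounding policy {policy!r}")
    if subquantum not in ("clamp", "drop"):
        raise ValidationError(f"unknown subquantum policy {subquantum!r}")
    ratio = table.lengths / scale.l_um
    # exact multiples of the quantum must land on their own class even under
    # float round-off, so snap near-integer ratios before applying ceil
    nearest_int = np.rint(ratio)
    snapped = np.where(np.abs(ratio - nearest_int) < 1e-9, nearest_int, ratio)
    if policy == "nearest":
        classes = _round_nearest_away(snapped)
    else:
        classes = np.ceil(snapped)
    df = table.df.copy()
    if subquantum == "clamp":
        classes = np.maximum(classes, 1)
        df["quanta_class"] = classes.astype(np.int64)
        return LengthTable(df, n_rejected=table.n_rejected)
    keep = classes >= 1
    df = df.loc[keep].copy()
    if len(df) == 0:
        raise EmptyInputError("all records fell below half a quantum and were dropped")
    df["quanta_class"] = classes[keep].astype(np.int64)
    return LengthTable(df, n_rejected=table.n_rejected + int((~keep).sum()))


def empirical_distribution(
    table: LengthTable,
    condition: str | None = None,
    compartment: str | None = None,
    cell_id=None,
) -> SizeDistribution:
    """Empirical size-class distribution of (a filtered subset of) a
    quantized table."""
    df = table.df
    if "quanta_class" not in df.columns:
        raise ValidationError("table is not quantized; call quantize_lengths first")
    if condition is not None:
        df = df[df["condition"] == condition]
    if compartment is not None:
        df = df[df["compartment"] == compartment]
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    if len(df) == 0:
        raise EmptyInputError("no records pass the requested filters")
    counts = df["quanta_class"].value_counts().to_dict()
    return SizeDistribution.from_counts(counts)


def long_fraction(table: LengthTable, threshold_um: float = 2.0) -> float:
    """Fraction of organelles strictly longer than ``threshold_um``."""
    if threshold_um < 0:
        raise ValidationError("threshold must be non-negative")
    lengths = table.lengths
    if lengths.size == 0:
        raise EmptyInputError("empty length table")
    return float((lengths > threshold_um).mean())
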