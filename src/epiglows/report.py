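"""Per-sample and per-kit summary tables (depth, breadth, variant counts).

Groups per-sample sequencing summaries by library kit and reports the
mean and sample (n-1) standard deviation of depth and variant count.
Display formatting offers both half-away-from-zero rounding and
truncation, since published summary tables mix the two conventions.

A bundled example table of 28 Holstein low-pass nanopore samples across
three library kits (LSK109, Q20, LSK114) ships with the package.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_kit_samples", "summarize_samples", "format_value"]

SAMPLE_COLUMNS = ["sample", "kit", "depth", "breadth", "n_variants"]


def load_kit_samples() -> pd.DataFrame:
    """Bundled per-sample summaries: kit, mean depth, breadth %, variant count."""
    with resources.files("epiglows.data").joinpath("kit_samples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_samples(
    samples: pd.DataFrame,
    group_col: str = "kit",
    value_cols: tuple[str, ...] = ("depth", "breadth", "n_variants"),
) -> pd.DataFrame:
    """Group means and n-1 standard deviations per kit.

    Returns one row per group with ``<col>_mean``, ``<col>_sd`` and
    ``n_samples``; the sd is NaN for single-sample groups. Empty groups
    cannot occur (groupby drops them); an empty input is an error.
    """
    if samples.empty:
        raise ValueError("no samples to summarize")
    missing = {group_col, *value_cols} - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for group, sub in samples.groupby(group_col, sort=False):
        row = {group_col: group, "n_samples": len(sub)}
        for col in value_cols:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def format_value(value: float, decimals: int = 1, mode: str = "round") -> float:
    """Format a summary value at fixed precision.

    mode "round" is half-away-from-zero (so 0.25 -> 0.3 at one
    decimal, unlike banker's rounding); mode "truncate" drops digits
    toward zero (2.17 -> 2.1).
    """
    if not math.isfinite(value):
        return value
    scale = 10 ** decimals
    if mode == "round":
        return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale
    if mode == "truncate":
        return math.trunc(value * scale) / scale
    raise ValueError(f"unknown mode {mode!r}")
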