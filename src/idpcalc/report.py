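"""Ensemble-level QC: per-restraint distribution statistics and plots.

Back-calculated values are per conformer; before any reweighting it is useful
to know, restraint by restraint, where the pool's distribution sits relative
to the experimental range. ``summarize`` computes per-row mean/SD/min/max
(population SD, non-null values only) and, when experimental ranges are
supplied, the fraction of conformers falling inside the inclusive
[lower, upper] interval. ``plot_summary`` renders the distribution per
restraint: conformer values as red dots over grey experimental-range boxes
for distance/efficiency datatypes, histograms for J-couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .templates import BackcalcResult


@dataclass(frozen=True)
class ExperimentalRange:
    index: int
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise SchemaError(f"range row {self.index}: lower {self.lower} > upper {self.upper}")


def read_ranges(path) -> list[ExperimentalRange]:
    """Read a row-aligned lower,upper CSV of experimental ranges."""
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("lower", "upper"):
        if col not in df.columns:
            raise SchemaError(f"{path}: ranges file needs a {col!r} column")
    return [
        ExperimentalRange(i, float(r["lower"]), float(r["upper"]))
        for i, r in enumerate(df.to_dict("records"))
    ]


def _value_matrix(result: BackcalcResult) -> np.ndarray:
    """(n_conformers, n_rows) float matrix, NaN for nulls."""
    rows = [
        [np.nan if v is None else float(v) for v in values]
        for values in result.per_conformer.values()
    ]
    return np.asarray(rows, dtype=float)


def summarize(result: BackcalcResult, ranges: list[ExperimentalRange] | None = None) -> pd.DataFrame:
    """Per-restraint distribution statistics across conformers.

    Returns a DataFrame indexed by template row with columns ``mean``, ``sd``,
    ``min``, ``max``, ``n_null`` and — when ranges are given — ``frac_within``
    (inclusive bounds, computed over non-null values).
    """
    matrix = _value_matrix(result)
    if matrix.size == 0:
        raise InputError("result holds no conformers")
    n_rows = matrix.shape[1]
    if ranges is not None and len(ranges) != n_rows:
        raise InputError(f"{len(ranges)} ranges for {n_rows} template rows")

    with np.errstate(invalid="ignore"):
        summary = pd.DataFrame({
            "mean": np.nanmean(matrix, axis=0),
            "sd": np.nanstd(matrix, axis=0, ddof=0),
            "min": np.nanmin(matrix, axis=0),
            "max": np.nanmax(matrix, axis=0),
            "n_null": np.isnan(matrix).sum(axis=0),
        })
    if ranges is not None:
        fracs = []
        for j, rng in enumerate(ranges):
            col = matrix[:, j]
            valid = col[~np.isnan(col)]
            inside = np.sum((valid >= rng.lower) & (valid <= rng.upper))
            fracs.append(inside / len(valid) if len(valid) else np.nan)
        summary["frac_within"] = fracs
    return summary


def plot_summary(result: BackcalcResult, ranges: list[ExperimentalRange] | None,
                 out_path) -> Path:
    """Write one figure for the datatype (PNG/SVG chosen by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = _value_matrix(result)
    n_rows = matrix.shape[1]
    out_path = Path(out_path)

    if result.datatype == "jc":
        ncols = min(n_rows, 5)
        nrows = int(np.ceil(n_rows / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                                 squeeze=False)
        for j in range(n_rows):
            ax = axes[j // ncols][j % ncols]
            col = matrix[:, j]
            ax.hist(col[~np.isnan(col)], bins=20, color="firebrick")
            ax.set_title(f"row {j}", fontsize=8)
            ax.set_xlabel("J (Hz)", fontsize=7)
        for j in range(n_rows, nrows * ncols):
            axes[j // ncols][j % ncols].axis("off")
    else:
        fig, ax = plt.subplots(figsize=(max(6, 0.4 * n_rows), 4))
        if ranges is not None:
            for rng in ranges:
                ax.bar(rng.index, rng.upper - rng.lower, bottom=rng.lower,
                       width=0.8, color="0.8", zorder=1)
        for j in range(n_rows):
            col = matrix[:, j]
            col = col[~np.isnan(col)]
            ax.plot(np.full(col.shape, j), col, ".", color="red",
                    markersize=3, alpha=0.6, zorder=2)
        ax.set_xlabel("template row")
        unit = "distance (Å)" if result.datatype in ("pre", "noe") else "efficiency"
        ax.set_ylabel(unit)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
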