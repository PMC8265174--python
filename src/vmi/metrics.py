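"""Quantitative validation: Dice overlap and cube-law branching analysis.

The branching analysis compares, per depth, the summed cubed diameters of
parent vessels against those of the next depth's daughter vessels, then fits
a line through the (parent, daughter) pairs.  A network obeying the
minimum-work branching rule lies on the identity line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vmi.tracing import VesselTree
from vmi.volume_io import VesselMask

logger = logging.getLogger(__name__)


@dataclass
class DiceResult:
    """Dice overlap between two masks: 2|A∩B| / (|A| + |B|)."""

    dice: float
    size_a: int
    size_b: int
    intersection: int


@dataclass
class DepthRow:
    """Cubed-diameter sums linking depth ``k`` parents to depth ``k+1`` daughters."""

    depth: int
    parent_cubed_sum: float  # µm³
    daughter_cubed_sum: float  # µm³
    n_parents: int
    n_daughters: int


@dataclass
class MurrayResult:
    """Per-depth cubed-diameter sums and the fitted line against the identity."""

    depth_rows: list[DepthRow]
    slope: float
    intercept: float  # µm³
    r_squared: float
    exclude_terminal_parents: bool


def dice(a: VesselMask, b: VesselMask) -> DiceResult:
    """Dice coefficient between two shape-matched masks.

    Both masks empty is a 0/0 degenerate case, defined here as 0 with a
    warning.

    Raises
    ------
    ValueError
        On shape mismatch.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    size_a = int(np.count_nonzero(a.voxels))
    size_b = int(np.count_nonzero(b.voxels))
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    if size_a + size_b == 0:
        warnings.warn("Dice of two empty masks is undefined (0/0); returning 0.0")
        return DiceResult(0.0, 0, 0, 0)
    return DiceResult(2.0 * inter / (size_a + size_b), size_a, size_b, inter)


def _depth_sums_from_frame(
    df: pd.DataFrame, exclude_terminal_parents: bool
) -> list[DepthRow]:
    depths = sorted(df["depth"].unique())
    if len(depths) < 2:
        raise ValueError("branching analysis needs at least two depths")
    rows: list[DepthRow] = []
    for k in depths:
        if k + 1 not in depths:
            continue
        parents = df[df["depth"] == k]
        if exclude_terminal_parents:
            parents = parents[~parents["is_terminal"]]
        daughters = df[df["depth"] == k + 1]
        rows.append(
            DepthRow(
                depth=int(k),
                parent_cubed_sum=float((parents["mean_diameter_um"] ** 3).sum()),
                daughter_cubed_sum=float((daughters["mean_diameter_um"] ** 3).sum()),
                n_parents=len(parents),
                n_daughters=len(daughters),
            )
        )
    return rows


def murray_depth_sums(
    tree: "VesselTree | pd.DataFrame", exclude_terminal_parents: bool = False
) -> list[DepthRow]:
    """Per-depth cubed-diameter sums pairing depth ``k`` with depth ``k+1``.

    With ``exclude_terminal_parents=False`` (the reporting default) terminal
    branches at depth ``k`` are counted as parents even though they contribute
    no daughters, biasing the parent sum high; ``True`` removes them and
    quantifies that bias.

    Accepts a :class:`~vmi.tracing.VesselTree` or a branch table with columns
    ``depth``, ``mean_diameter_um``, ``is_terminal``.

    Raises
    ------
    ValueError
        If fewer than two depths are present.
    """
    if isinstance(tree, pd.DataFrame):
        df = tree
    else:
        df = pd.DataFrame(
            {
                "depth": [b.depth for b in tree.branches],
                "mean_diameter_um": [b.mean_diameter for b in tree.branches],
                "is_terminal": [b.is_terminal for b in tree.branches],
            }
        )
    return _depth_sums_from_frame(df, exclude_terminal_parents)


def murray_fit(
    depth_rows: list[DepthRow], exclude_terminal_parents: bool = False
) -> MurrayResult:
    """Ordinary least-squares fit of daughter sums on parent sums.

    Compliance with the cube law means slope ≈ 1, intercept ≈ 0, and high r²
    (the identity line); the caller judges closeness.

    Raises
    ------
    ValueError
        With fewer than two rows or zero variance in the parent sums.
    """
    if len(depth_rows) < 2:
        raise ValueError("need at least two depth rows to fit a line")
    x = np.array([r.parent_cubed_sum for r in depth_rows])
    y = np.array([r.daughter_cubed_sum for r in depth_rows])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in parent sums; line fit undefined")
    res = stats.linregress(x, y)
    return MurrayResult(
        depth_rows=list(depth_rows),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        exclude_terminal_parents=exclude_terminal_parents,
    )


def murray_analysis(
    tree: "VesselTree | pd.DataFrame", exclude_terminal_parents: bool = False
) -> MurrayResult:
    """Convenience wrapper: depth sums followed by the line fit."""
    rows = murray_depth_sums(tree, exclude_terminal_parents)
    return murray_fit(rows, exclude_terminal_parents)


def murray_table(result: MurrayResult) -> pd.DataFrame:
    """Depth rows as a DataFrame (one row per parent depth)."""
    return pd.DataFrame(
        [
            {
                "depth": r.depth,
                "parent_cubed_sum_um3": r.parent_cubed_sum,
                "daughter_cubed_sum_um3": r.daughter_cubed_sum,
                "n_parents": r.n_parents,
                "n_daughters": r.n_daughters,
            }
            for r in result.depth_rows
        ]
    )


def vascular_volume_fraction(
    mask: VesselMask, tissue: VesselMask | None = None
) -> float:
    """Vessel voxels as a fraction of tissue voxels (or of the whole grid).

    Raises
    ------
    ValueError
        On shape mismatch or an empty tissue mask.
    """
    n_vessel = int(np.count_nonzero(mask.voxels))
    if tissue is None:
        return n_vessel / mask.voxels.size
    if tissue.shape != mask.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {tissue.shape}")
    n_tissue = int(np.count_nonzero(tissue.voxels))
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    return n_vessel / n_tissue
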