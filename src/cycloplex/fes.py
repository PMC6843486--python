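"""Boltzmann-inversion free-energy surfaces over rim-geometry coordinates.

A sampled 2-D distribution P(x, y) — here the adjacent-unit rim distances
(dO3-2, dO4-4) — is binned and inverted into a free-energy surface

    F(x, y) = -R T ln P(x, y)

with the natural logarithm and the molar gas constant in kcal/mol (so R*T
is the thermal energy per mole), shifted so the global minimum of the
occupied bins is zero.  Empty bins carry +inf.  Rectangular basin
definitions (the compact H-bonded M1 basin, the glucopyranose-rotation M2
basin, the doubly-lengthened M3 basin) receive occupancies equal to the
probability mass falling inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solubility import GAS_CONSTANT_KCAL

__all__ = [
    "PESGrid",
    "BasinLabel",
    "BasinDefinitionError",
    "pes_2d",
    "assign_basins",
    "DEFAULT_BASINS",
    "plot_pes",
]


class BasinDefinitionError(ValueError):
    """Basin rectangles overlap or are malformed."""


#: label -> (x_range, y_range) in A over (dO3-2, dO4-4)
DEFAULT_BASINS = {
    "M1": ((2.5, 4.5), (4.1, 4.9)),
    "M2": ((4.5, 5.5), (4.5, 5.2)),
    "M3": ((4.5, 5.5), (5.5, 6.5)),
}


@dataclass
class PESGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) raw histogram counts
    free_energy: np.ndarray  # (nx, ny) kcal/mol, min-shifted; empty = +inf
    temperature: float  # K
    rt: float  # kcal/mol
    n_samples: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (x_center, y_center, F) table; +inf serialized as 'inf'."""
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        f = self.free_energy.ravel()
        return pd.DataFrame(
            {
                "x_center": xc.ravel(),
                "y_center": yc.ravel(),
                "F_kcal_mol": [v if np.isfinite(v) else "inf" for v in f],
            }
        )


@dataclass
class BasinLabel:
    label: str
    x_range: tuple
    y_range: tuple
    occupancy: float


def pes_2d(
    x,
    y,
    *,
    bins=None,
    x_range=(2.0, 7.0),
    y_range=(3.5, 7.0),
    bin_width: float = 0.1,
    temperature: float = 303.0,
    r_constant: float = GAS_CONSTANT_KCAL,
) -> PESGrid:
    """Bin (x, y) samples and Boltzmann-invert the histogram.

    ``bins`` may give explicit (x_edges, y_edges); otherwise a regular grid
    of ``bin_width`` over ``x_range`` x ``y_range`` is used.  Samples
    outside the grid are excluded from the histogram but still count in the
    normalization, so occupancies refer to the full sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    if len(x) == 0:
        raise ValueError("no samples to histogram")
    if bins is None:
        x_edges = np.arange(x_range[0], x_range[1] + 0.5 * bin_width, bin_width)
        y_edges = np.arange(y_range[0], y_range[1] + 0.5 * bin_width, bin_width)
    else:
        x_edges, y_edges = (np.asarray(b, dtype=float) for b in bins)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    if not counts.any():
        raise ValueError("no samples fall inside the grid")
    rt = r_constant * temperature
    with np.errstate(divide="ignore"):
        f = -rt * np.log(counts / len(x))
    f = np.where(counts > 0, f, np.inf)
    f -= f[np.isfinite(f)].min()
    return PESGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts.astype(int),
        free_energy=f,
        temperature=temperature,
        rt=rt,
        n_samples=len(x),
    )


def _overlap(a, b) -> bool:
    (ax0, ax1), (ay0, ay1) = a
    (bx0, bx1), (by0, by1) = b
    return (min(ax1, bx1) - max(ax0, bx0) > 0) and (min(ay1, by1) - max(ay0, by0) > 0)


def assign_basins(grid: PESGrid, basin_definitions=None) -> list[BasinLabel]:
    """Probability mass of each rectangular basin, by bin centers.

    Rectangles must be pairwise non-overlapping (positive-area overlap).
    """
    defs = dict(basin_definitions or DEFAULT_BASINS)
    items = list(defs.items())
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if _overlap(items[i][1], items[j][1]):
                raise BasinDefinitionError(
                    f"basins {items[i][0]!r} and {items[j][0]!r} overlap"
                )
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    out = []
    for label, ((x0, x1), (y0, y1)) in items:
        inside = (xc >= x0) & (xc < x1) & (yc >= y0) & (yc < y1)
        occ = grid.counts[inside].sum() / grid.n_samples
        out.append(BasinLabel(label=label, x_range=(x0, x1),
                              y_range=(y0, y1), occupancy=float(occ)))
    return out


def plot_pes(grid: PESGrid, path, *, f_max: float | None = None) -> None:
    """Render the surface as a heatmap image (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = np.ma.masked_invalid(grid.free_energy)
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, f.T,
                         cmap="viridis", vmax=f_max, shading="flat")
    fig.colorbar(mesh, ax=ax, label="F (kcal/mol)")
    ax.set_xlabel("dO3-2 (Å)")
    ax.set_ylabel("dO4-4 (Å)")
    ax.set_title(f"Free-energy surface at {grid.temperature:g} K")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
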