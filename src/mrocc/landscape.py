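"""Landscape-configuration covariates from binary habitat grids.

Two metrics feed the region covariate table: total forest cover (hectares)
and the mean radius of gyration of forest patches (metres) — the mean
distance from each cell of a patch to the patch centroid, averaged over
patches. Patches are connected components of forest cells (8-neighbour by
default, the convention of common landscape-metrics tooling; 4-neighbour
available). Coordinates are cell centres; the centroid is their mean.

Grids are plain 0/1 rasters read from CSV or ESRI ASCII (.asc).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryGrid",
    "PatchSet",
    "label_patches",
    "forest_cover",
    "mean_radius_of_gyration",
]


@dataclass
class BinaryGrid:
    """0/1 habitat raster with a square cell size in metres."""

    cells: np.ndarray
    cell_size: float  # metres per cell edge

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("grid cells must be 0 or 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, cell_size: float) -> "BinaryGrid":
        return cls(np.loadtxt(path, delimiter=",", dtype=int), cell_size)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.cells, fmt="%d", delimiter=",")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "BinaryGrid":
        """Read an ESRI ASCII grid; nodata cells become 0."""
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        arr = np.asarray(rows)
        nodata = header.get("nodata_value")
        if nodata is not None:
            arr = np.where(arr == nodata, 0.0, arr)
        return cls((arr > 0).astype(int), header.get("cellsize", 1.0))


@dataclass
class PatchSet:
    """Connected forest patches: per-cell labels (0 = matrix), counts,
    centroids in metres (cell-centre coordinates)."""

    labels: np.ndarray
    n_patches: int
    cell_size: float

    def patch_cells(self, label: int) -> np.ndarray:
        """(k, 2) centre coordinates in metres of one patch's cells."""
        rows, cols = np.nonzero(self.labels == label)
        return (np.column_stack([rows, cols]) + 0.5) * self.cell_size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_patches + 1)[1:]


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def label_patches(grid: BinaryGrid, connectivity: int = 8) -> PatchSet:
    """Label connected components of forest cells (4- or 8-neighbour)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(grid.cells, structure=_STRUCTURES[connectivity])
    return PatchSet(labels=labels, n_patches=int(n), cell_size=grid.cell_size)


def forest_cover(grid: BinaryGrid) -> float:
    """Total forest area in hectares: cells * cell_size^2 / 10,000."""
    return float(grid.cells.sum()) * grid.cell_size**2 / 10_000.0


def mean_radius_of_gyration(
    patches: PatchSet, area_weighted: bool = False
) -> float:
    """Mean radius of gyration over patches, in metres.

    Per patch: the mean Euclidean distance from each cell centre to the patch
    centroid (0 for a single-cell patch). Patches averaged unweighted by
    default; ``area_weighted=True`` weights by cell count. NaN with no
    patches (undefined).
    """
    if patches.n_patches == 0:
        return float("nan")
    rows, cols = np.nonzero(patches.labels)
    labs = patches.labels[rows, cols]
    pts = (np.column_stack([rows, cols]) + 0.5) * patches.cell_size
    order = np.argsort(labs, kind="stable")
    labs, pts = labs[order], pts[order]
    counts = np.bincount(labs, minlength=patches.n_patches + 1)[1:]
    gyr = np.empty(patches.n_patches)
    start = 0
    for i, c in enumerate(counts):
        cells = pts[start: start + c]
        centroid = cells.mean(axis=0)
        gyr[i] = np.linalg.norm(cells - centroid, axis=1).mean()
        start += c
    if area_weighted:
        return float(np.average(gyr, weights=counts))
    return float(gyr.mean())
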