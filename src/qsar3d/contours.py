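"""StDev*Coefficient contour fields and favorable/unfavorable regions.

For each retained descriptor column the product sd(X_j) * b_j is mapped back
onto its grid point (masked points carry exactly 0). Points above/below
percentile levels of the nonzero value distribution are grouped into
6-connected regions, the analog of the green/yellow contour volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fields import GridSpec, write_grid_map
from .pls import PLSModel

__all__ = [
    "ContourField",
    "Region",
    "ContourError",
    "stdev_coeff_field",
    "extract_regions",
    "export_regions",
]


class ContourError(RuntimeError):
    pass


@dataclass
class Region:
    """One connected set of contour points."""

    region_id: int
    sign: str  # "favorable" | "unfavorable"
    point_indices: np.ndarray  # flat grid indices
    centroid: tuple[float, float, float]

    @property
    def size(self) -> int:
        return int(self.point_indices.size)


@dataclass
class ContourField:
    """Per-grid-point sd*coefficient values for one field kind."""

    kind: str
    grid: GridSpec
    values: np.ndarray  # (n_points,), 0 at masked columns
    favorable_level: float | None = None
    unfavorable_level: float | None = None

    def write(self, path: str | Path) -> None:
        write_grid_map(self.grid, self.values, path)


def stdev_coeff_field(
    model: PLSModel,
    X: np.ndarray,
    index_map: Sequence[tuple[str, int]],
    kind: str,
    grid: GridSpec,
) -> ContourField:
    """Map sd(X_j) * b_j back onto the grid for one field kind."""
    if len(index_map) != model.n_columns:
        raise ContourError("index map length does not match model columns")
    kinds = {k for k, _ in index_map}
    if kind not in kinds:
        raise ContourError(f"field kind {kind!r} not in index map (have {sorted(kinds)})")
    X = np.asarray(X, dtype=float)
    values = np.zeros(grid.n_points)
    for j, (k, gidx) in enumerate(index_map):
        if k == kind:
            values[gidx] = X[:, j].std(ddof=0) * float(model.coef[j])
    return ContourField(kind=kind, grid=grid, values=values)


def extract_regions(
    field: ContourField,
    fav_percentile: float = 80.0,
    unfav_percentile: float = 20.0,
) -> list[Region]:
    """Label 6-connected favorable/unfavorable point groups.

    Levels are percentiles of the nonzero value distribution; a constant
    (or all-zero) field yields no regions and a warning.
    """
    if fav_percentile < unfav_percentile:
        raise ContourError("favorable percentile must be >= unfavorable percentile")
    nz = field.values[field.values != 0.0]
    if nz.size == 0 or np.ptp(nz) == 0:
        warnings.warn(f"contour field {field.kind} is constant; no regions extracted")
        return []
    fav_level = float(np.percentile(nz, fav_percentile))
    unfav_level = float(np.percentile(nz, unfav_percentile))
    field.favorable_level = fav_level
    field.unfavorable_level = unfav_level
    cube = field.values.reshape(field.grid.dims)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-neighborhood
    regions: list[Region] = []
    next_id = 0
    points = field.grid.points()
    for sign, mask in (
        ("favorable", (cube >= fav_level) & (cube != 0.0)),
        ("unfavorable", (cube <= unfav_level) & (cube != 0.0)),
    ):
        labeled, n_comp = ndimage.label(mask, structure=structure)
        for comp in range(1, n_comp + 1):
            flat = np.flatnonzero(labeled.ravel() == comp)
            centroid = points[flat].mean(axis=0)
            regions.append(
                Region(
                    region_id=next_id,
                    sign=sign,
                    point_indices=flat,
                    centroid=tuple(float(v) for v in centroid),
                )
            )
            next_id += 1
    return regions


def export_regions(regions: list[Region], path: str | Path) -> None:
    payload = [
        {
            "id": r.region_id,
            "sign": r.sign,
            "n_points": r.size,
            "centroid": list(r.centroid),
            "point_indices": r.point_indices.tolist(),
        }
        for r in regions
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
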