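"""Grid-based molecular interaction fields and descriptor assembly.

Two field families are computed on a shared rectangular grid around the
aligned ensemble:

* CoMFA-style: Lennard-Jones 6-12 steric energies (probe = sp3 carbon) and
  Coulomb electrostatics with a distance-dependent dielectric, both clipped
  at +/-30 kcal/mol; electrostatic values at sterically excluded points are
  replaced by the column mean over the non-excluded compounds.
* CoMSIA-style: Gaussian-attenuated similarity indices
  ``A(j) = -sum_i w_probe * w_i * exp(-alpha * r_ij^2)`` for steric
  (vdW-radius-cubed weights), electrostatic (partial charges), hydrophobic
  (Crippen contributions) and H-bond donor/acceptor (flag weights).

Low-variance columns are masked out before modeling and each field block is
scaled by its overall standard deviation so no field dominates by variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .conformers import Molecule3D, lj_epsilon

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "FieldError",
    "COMFA_KINDS",
    "COMSIA_KINDS",
    "build_grid",
    "comfa_fields",
    "comfa_blocks",
    "comsia_fields",
    "comsia_blocks",
    "filter_columns",
    "assemble_descriptors",
    "write_grid_map",
    "read_grid_map",
]

COMFA_KINDS = ("CoMFA_S", "CoMFA_E")
COMSIA_KINDS = ("CoMSIA_S", "CoMSIA_E", "CoMSIA_H", "CoMSIA_D", "CoMSIA_A")

COULOMB_CONSTANT = 332.0  # kcal*A/(mol*e^2)


class FieldError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid; points enumerated with z varying fastest."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) coordinates in fixed lexicographic (x, y, z) order."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def translate(self, shift: Sequence[float]) -> "GridSpec":
        o = tuple(float(a + b) for a, b in zip(self.origin, shift))
        return GridSpec(origin=o, spacing=self.spacing, dims=self.dims)


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom and field-evaluation parameters."""

    steric_radius: float = 1.7  # sp3 carbon vdW radius, A
    steric_epsilon: float = 0.107  # kcal/mol
    charge: float = 1.0  # +1 e
    hydrophobic_weight: float = 1.0
    donor_weight: float = 1.0
    acceptor_weight: float = 1.0
    alpha: float = 0.3  # CoMSIA attenuation, 1/A^2
    energy_cutoff: float = 30.0  # kcal/mol

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise FieldError("CoMSIA attenuation alpha must be positive")
        if self.energy_cutoff <= 0:
            raise FieldError("energy cutoff must be positive")


@dataclass
class FieldBlock:
    """A (compounds x grid points) matrix for one field kind."""

    kind: str
    matrix: np.ndarray
    mask: np.ndarray  # bool, True = column retained
    scale: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise FieldError(f"non-finite values in {self.kind} block")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.matrix.shape[1],):
            raise FieldError("mask length must equal the number of grid points")

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def build_grid(
    mols: Iterable[Molecule3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Bounding box of all atoms, expanded by ``margin`` on every side and
    snapped outward onto the global ``spacing`` lattice."""
    mols = list(mols)
    if not mols:
        raise FieldError("build_grid requires at least one molecule")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = tuple(int(np.ceil((h - o) / spacing - 1e-9)) + 1 for h, o in zip(hi, origin))
    return GridSpec(origin=tuple(float(v) for v in origin), spacing=float(spacing), dims=dims)


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_fields(
    mol: Molecule3D, grid: GridSpec, probe: ProbeSpec | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CoMFA steric and electrostatic values at every grid point.

    Returns ``(steric, electrostatic, excluded)``; ``excluded`` marks points
    where the steric energy hit the positive cutoff (inside the molecular
    envelope). Both energy arrays are clipped to +/-cutoff, so values are
    finite even at points coincident with atoms.
    """
    probe = probe or ProbeSpec()
    if mol.charges is None or mol.vdw_radius is None:
        raise FieldError(f"molecule {mol.abbrev} lacks charge/radius annotations")
    d = _distances(grid.points(), mol.coords)
    d = np.maximum(d, 1e-12)
    r_min = mol.vdw_radius + probe.steric_radius
    eps = np.sqrt(lj_epsilon(mol.elements) * probe.steric_epsilon)
    sr2 = (r_min[None, :] / d) ** 2
    sr6 = np.minimum(sr2**3, 1e12)  # cap per-term repulsion before summing
    lj = eps[None, :] * (sr6 * sr6 - 2.0 * sr6)
    steric = np.clip(lj.sum(axis=1), -probe.energy_cutoff, probe.energy_cutoff)
    excluded = steric >= probe.energy_cutoff
    coulomb = COULOMB_CONSTANT * probe.charge * mol.charges[None, :] / (d * d)
    electrostatic = np.clip(coulomb.sum(axis=1), -probe.energy_cutoff, probe.energy_cutoff)
    return steric, electrostatic, excluded


def comfa_blocks(
    mols: Sequence[Molecule3D], grid: GridSpec, probe: ProbeSpec | None = None
) -> tuple[FieldBlock, FieldBlock]:
    """Stack per-molecule CoMFA fields into S and E blocks.

    Electrostatic entries at sterically excluded points are replaced by the
    column mean over non-excluded compounds (0 where all are excluded).
    """
    probe = probe or ProbeSpec()
    steric_rows, elec_rows, excl_rows = [], [], []
    for m in mols:
        s, e, x = comfa_fields(m, grid, probe)
        steric_rows.append(s)
        elec_rows.append(e)
        excl_rows.append(x)
    S = np.vstack(steric_rows)
    E = np.vstack(elec_rows)
    X = np.vstack(excl_rows)
    n_ok = (~X).sum(axis=0)
    col_sum = np.where(~X, E, 0.0).sum(axis=0)
    col_mean = np.divide(col_sum, n_ok, out=np.zeros_like(col_sum), where=n_ok > 0)
    E = np.where(X, col_mean[None, :], E)
    full = np.ones(grid.n_points, dtype=bool)
    return (
        FieldBlock("CoMFA_S", S, full.copy()),
        FieldBlock("CoMFA_E", E, full.copy()),
    )


def comsia_fields(
    mol: Molecule3D, grid: GridSpec, probe: ProbeSpec | None = None
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices for the five CoMSIA properties."""
    probe = probe or ProbeSpec()
    missing = [
        name
        for name in ("charges", "hydrophobic", "vdw_radius", "donor", "acceptor")
        if getattr(mol, name) is None
    ]
    if missing:
        raise FieldError(f"molecule {mol.abbrev} lacks annotations: {missing}")
    d2 = np.sum((grid.points()[:, None, :] - mol.coords[None, :, :]) ** 2, axis=2)
    g = np.exp(-probe.alpha * d2)
    weights = {
        "CoMSIA_S": 1.0 * mol.vdw_radius**3,
        "CoMSIA_E": probe.charge * mol.charges,
        "CoMSIA_H": probe.hydrophobic_weight * mol.hydrophobic,
        "CoMSIA_D": probe.donor_weight * mol.donor.astype(float),
        "CoMSIA_A": probe.acceptor_weight * mol.acceptor.astype(float),
    }
    return {kind: -(g @ w) for kind, w in weights.items()}


def comsia_blocks(
    mols: Sequence[Molecule3D], grid: GridSpec, probe: ProbeSpec | None = None
) -> list[FieldBlock]:
    probe = probe or ProbeSpec()
    rows = [comsia_fields(m, grid, probe) for m in mols]
    full = np.ones(grid.n_points, dtype=bool)
    return [
        FieldBlock(kind, np.vstack([r[kind] for r in rows]), full.copy())
        for kind in COMSIA_KINDS
    ]


def filter_columns(block: FieldBlock, min_sigma: float) -> FieldBlock:
    """Mask columns whose standard deviation across compounds is below
    ``min_sigma``; the mask is retained for contour back-mapping."""
    sd = block.matrix.std(axis=0, ddof=0)
    mask = sd >= min_sigma if min_sigma > 0 else np.ones_like(sd, dtype=bool)
    if not mask.any():
        raise FieldError(
            f"all {block.kind} columns masked at min_sigma={min_sigma}; lower the threshold"
        )
    return replace(block, mask=mask)


def assemble_descriptors(
    blocks: Sequence[FieldBlock], scaling: bool = True
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Concatenate retained columns into one X matrix with block scaling.

    Each block's retained submatrix is divided by its overall (flattened)
    standard deviation when ``scaling`` is on; the returned index map is a
    bijection column -> (field kind, grid point index).
    """
    if not blocks:
        raise FieldError("no field blocks to assemble")
    n = blocks[0].matrix.shape[0]
    parts: list[np.ndarray] = []
    index_map: list[tuple[str, int]] = []
    for block in blocks:
        if block.matrix.shape[0] != n:
            raise FieldError(
                f"block {block.kind} has {block.matrix.shape[0]} compounds, expected {n}"
            )
        sub = block.matrix[:, block.mask]
        scale = float(sub.std(ddof=0))
        if scaling and scale > 0:
            sub = sub / scale
        block.scale = scale if scaling else 1.0
        parts.append(sub)
        index_map.extend((block.kind, int(j)) for j in np.flatnonzero(block.mask))
    return np.hstack(parts), index_map


def write_grid_map(grid: GridSpec, values: np.ndarray, path: str | Path) -> None:
    """Plain-text grid map: header (origin, spacing, dims), then one value
    per line in the grid's lexicographic point order."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_points,):
        raise FieldError("value array does not match grid size")
    with open(path, "w") as fh:
        fh.write(f"# origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}\n")
        fh.write(f"# spacing {grid.spacing:.6f}\n")
        fh.write(f"# dims {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n")
        for v in values:
            fh.write(f"{float(v)!r}\n")


def read_grid_map(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    lines = Path(path).read_text().splitlines()
    origin = tuple(float(v) for v in lines[0].split()[2:5])
    spacing = float(lines[1].split()[2])
    dims = tuple(int(v) for v in lines[2].split()[2:5])
    values = np.array([float(v) for v in lines[3:]], dtype=float)
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    if values.shape != (grid.n_points,):
        raise FieldError("grid map body does not match declared dims")
    return grid, values
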