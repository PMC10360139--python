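"""Voxel-wise RBE-weighted dose maps from co-registered dose and LET_d grids.

The scalar RBE prediction is mapped independently over every voxel of a
physical-dose grid (Gy per fraction) and a dose-weighted-LET grid
(keV/um) that share shape and spacing — no smoothing or interpolation.
RBE is evaluated at the voxel's per-fraction dose; total RBE-weighted
dose is the per-fraction result times the fraction count.  Dose and LET
scoring (Monte Carlo, CT import) happen upstream; grids arrive as plain
delimited text (2-D) or a JSON-header + flat binary container (3-D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .benchmarks import BenchmarkModelSpec, _rbe_ratios
from .flint import FlintModel, predict_endpoint
from .lqm import LQParams, _dose_for_logsf
from .selection import _reconstruct_vec

__all__ = ["ScalarGrid", "rbe_weighted_dose", "model_difference_map",
           "read_grid_2d", "write_grid_2d", "read_grid_3d", "write_grid_3d"]


@dataclass(frozen=True)
class ScalarGrid:
    """A 2-D or 3-D scalar field with per-axis spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim not in (2, 3):
            raise ValueError("grid must be 2-D or 3-D")
        if len(self.spacing) != v.ndim:
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("grid values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def aligned_with(self, other: "ScalarGrid") -> bool:
        return self.values.shape == other.values.shape and self.spacing == other.spacing


def _require_aligned(a: ScalarGrid, b: ScalarGrid) -> None:
    if not a.aligned_with(b):
        raise ValueError("grids must share shape and spacing")


def _flint_rbe_vec(dose: np.ndarray, let: np.ndarray, photon: LQParams, model: FlintModel):
    d1x = _dose_for_logsf(photon.alpha, photon.beta, -1.0)
    d2x = _dose_for_logsf(photon.alpha, photon.beta, -3.0)
    d1p = predict_endpoint(float(d1x), let, model.sf1_params)
    d2p = predict_endpoint(float(d2x), let, model.sf2_params)
    D = np.column_stack([d1p, d2p])
    logsf = np.tile([-1.0, -3.0], (let.size, 1))
    a_p, b_p = _reconstruct_vec(D, logsf)
    log_sf_d = -(a_p * dose + b_p * dose * dose)
    return _dose_for_logsf(photon.alpha, photon.beta, log_sf_d) / dose


def _benchmark_rbe_vec(dose, let, photon: LQParams, spec: BenchmarkModelSpec):
    rmax, rmin = _rbe_ratios(spec, photon.alpha_beta_ratio, let)
    a_p = photon.alpha * rmax
    b_p = photon.beta * rmin**2
    log_sf_d = -(a_p * dose + b_p * dose * dose)
    return _dose_for_logsf(photon.alpha, photon.beta, log_sf_d) / dose


def rbe_weighted_dose(
    dose: ScalarGrid,
    let: ScalarGrid,
    photon: LQParams,
    model: FlintModel | BenchmarkModelSpec,
    fractions: int = 1,
) -> ScalarGrid:
    """Voxel-wise RBE-weighted dose: dose x RBE(dose, LET_d) x fractions.

    ``photon`` supplies the tissue's reference LQ parameters (single
    tissue).  Zero-dose voxels short-circuit to 0: RBE is undefined at
    d = 0 and no dose means no weighted dose.
    """
    _require_aligned(dose, let)
    if fractions < 1:
        raise ValueError("fractions must be >= 1")
    d = dose.values.ravel()
    L = let.values.ravel()
    nz = d > 0
    rbe = np.ones_like(d)
    if np.any(nz):
        if isinstance(model, FlintModel):
            rbe[nz] = _flint_rbe_vec(d[nz], L[nz], photon, model)
        else:
            rbe[nz] = _benchmark_rbe_vec(d[nz], L[nz], photon, model)
    out = np.where(nz, d * rbe, 0.0) * fractions
    return ScalarGrid(values=out.reshape(dose.values.shape), spacing=dose.spacing)


def model_difference_map(grid_a: ScalarGrid, grid_b: ScalarGrid) -> ScalarGrid:
    """Voxel-wise arithmetic difference A - B (values may be negative)."""
    _require_aligned(grid_a, grid_b)
    diff = grid_a.values - grid_b.values
    out = object.__new__(ScalarGrid)
    object.__setattr__(out, "values", diff)
    object.__setattr__(out, "spacing", grid_a.spacing)
    return out


# ---------------------------------------------------------------------------
# Plain-text (2-D) and JSON-header + flat binary (3-D) grid I/O
# ---------------------------------------------------------------------------

def write_grid_2d(grid: ScalarGrid, path: str | Path) -> None:
    header = f"spacing_mm: {grid.spacing[0]} {grid.spacing[1]}"
    np.savetxt(path, grid.values, header=header)


def read_grid_2d(path: str | Path) -> ScalarGrid:
    first = Path(path).read_text().splitlines()[0]
    if not first.startswith("# spacing_mm:"):
        raise ValueError("missing spacing header line '# spacing_mm: dx dy'")
    spacing = tuple(float(v) for v in first.split(":")[1].split())
    return ScalarGrid(values=np.loadtxt(path), spacing=spacing)


def write_grid_3d(grid: ScalarGrid, path: str | Path) -> None:
    """JSON header `<path>.json` + float64 little-endian row-major `<path>.raw`."""
    if grid.values.ndim != 3:
        raise ValueError("write_grid_3d needs a 3-D grid")
    path = Path(path)
    meta = {
        "shape": list(grid.values.shape),
        "spacing_mm": list(grid.spacing),
        "dtype": "<f8",
        "order": "C",
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    grid.values.astype("<f8").tofile(path.with_suffix(".raw"))


def read_grid_3d(path: str | Path) -> ScalarGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.fromfile(path.with_suffix(".raw"), dtype=meta["dtype"]).reshape(meta["shape"])
    return ScalarGrid(values=values, spacing=tuple(meta["spacing_mm"]))
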