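"""One-dimensional current-source-density benchmark forward model.

A segment of current monopoles at depth 0 is observed by a parallel linear
electrode array at height ``h`` in an infinite homogeneous isotropic volume
conductor (conductivity 1). The potential of a unit monopole is the free-space
fundamental solution of Poisson's equation,

    V(x, y) = 1 / (4 pi sqrt(h^2 + (x - y)^2)),

so the forward matrix ``L`` has entries ``L[k, l] = V(x_l, y_k)`` for source
position ``x_l`` and electrode position ``y_k``. The singular system of ``L``
is precomputed because every estimator downstream is expressed in it.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGeometryError

__all__ = [
    "SourceGrid",
    "ElectrodeArray",
    "ForwardModel",
    "monopole_potential",
    "build_forward_model",
    "default_benchmark",
    "write_forward_model",
    "read_forward_model",
]

#: Nominal benchmark geometry: array length 4 mm, electrode spacing 0.4 mm,
#: array height 0.5 mm; segment length 4 mm, source spacing 0.2 mm.
DEFAULT_GEOMETRY = {
    "array_length": 4.0,
    "electrode_spacing": 0.4,
    "height": 0.5,
    "segment_length": 4.0,
    "source_spacing": 0.2,
}


def _centered_positions(length: float, spacing: float) -> np.ndarray:
    if length <= 0 or spacing <= 0:
        raise InvalidGeometryError(
            f"length and spacing must be positive (got {length}, {spacing})"
        )
    count = length / spacing
    n = int(round(count))
    if abs(count - n) > 1e-9:
        raise InvalidGeometryError(
            f"length {length} is not an integer multiple of spacing {spacing}"
        )
    return spacing * (np.arange(n + 1) - n / 2.0)


@dataclass(frozen=True)
class SourceGrid:
    """Evenly spaced 1-D source grid (mm), centered on 0, endpoints included."""

    length: float
    spacing: float
    positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", _centered_positions(self.length, self.spacing))

    @property
    def p(self) -> int:
        return self.positions.size

    def index_of(self, position_mm: float, atol: float = 1e-9) -> int:
        """Grid index of an on-grid coordinate; raises if off-grid."""
        hits = np.nonzero(np.abs(self.positions - position_mm) <= atol)[0]
        if hits.size != 1:
            raise InvalidGeometryError(f"{position_mm} mm is not on the source grid")
        return int(hits[0])


@dataclass(frozen=True)
class ElectrodeArray:
    """Evenly spaced 1-D electrode array (mm) at height ``height`` above the grid."""

    length: float
    spacing: float
    height: float
    positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidGeometryError(f"array height must be positive (got {self.height})")
        object.__setattr__(self, "positions", _centered_positions(self.length, self.spacing))

    @property
    def n(self) -> int:
        return self.positions.size


def monopole_potential(x, y, h):
    """Potential at electrode coordinate ``y`` of a unit monopole at ``x``.

    Parameters are in mm; ``h`` is the (positive) height of the electrode
    plane above the source line. Vectorized over ``x`` and ``y``.
    """
    h = float(h)
    if h <= 0:
        raise InvalidGeometryError(f"height must be positive (got {h})")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 1.0 / (4.0 * np.pi * np.sqrt(h * h + (x - y) ** 2))


@dataclass(frozen=True)
class ForwardModel:
    """Forward matrix with its singular system.

    ``L`` maps source strengths (p) to electrode potentials (n). The singular
    system ``L = U diag(D) V^T`` is truncated to the numerical rank ``r``.
    ``noise_unit`` is the largest eigenvalue of ``L L^T`` (= ``D[0]**2``); the
    simulator measures the sensor-noise variance in this unit.
    """

    grid: SourceGrid
    array: ElectrodeArray
    L: np.ndarray
    U: np.ndarray
    D: np.ndarray
    V: np.ndarray
    normalized: bool

    @property
    def n(self) -> int:
        return self.L.shape[0]

    @property
    def p(self) -> int:
        return self.L.shape[1]

    @property
    def r(self) -> int:
        return self.D.size

    @property
    def noise_unit(self) -> float:
        return float(self.D[0] ** 2)

    @property
    def full_row_rank(self) -> bool:
        return self.r == self.n

    def source_index(self, position_mm: float) -> int:
        return self.grid.index_of(position_mm)


def _singular_system(L: np.ndarray):
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    tol = s[0] * max(L.shape) * np.finfo(float).eps
    r = int(np.sum(s > tol))
    return U[:, :r], s[:r], Vt[:r].T


def build_forward_model(
    grid: SourceGrid, array: ElectrodeArray, normalize: bool = True
) -> ForwardModel:
    """Assemble ``L[k, l] = V(x_l, y_k)`` and its singular system.

    With ``normalize=True`` (default) ``L`` is divided by its largest singular
    value so that ``D[0] = 1`` and regularization levels are dimensionless.
    """
    if grid.p < 2:
        raise InvalidGeometryError("source grid needs at least 2 points")
    if array.n < 2:
        raise InvalidGeometryError("electrode array needs at least 2 electrodes")
    L = monopole_potential(grid.positions[np.newaxis, :], array.positions[:, np.newaxis], array.height)
    if normalize:
        L = L / np.linalg.svd(L, compute_uv=False)[0]
    U, D, V = _singular_system(L)
    return ForwardModel(grid=grid, array=array, L=L, U=U, D=D, V=V, normalized=normalize)


def default_benchmark(normalize: bool = True) -> ForwardModel:
    """The nominal benchmark: 11 electrodes over a 21-point source grid."""
    g = DEFAULT_GEOMETRY
    grid = SourceGrid(length=g["segment_length"], spacing=g["source_spacing"])
    array = ElectrodeArray(
        length=g["array_length"], spacing=g["electrode_spacing"], height=g["height"]
    )
    return build_forward_model(grid, array, normalize=normalize)


#: Nominal active-source locations (mm) of the two-source benchmark.
ACTIVE_SOURCE_POSITIONS = (-1.0, 1.0)


def write_forward_model(model: ForwardModel, path) -> None:
    """Write a ForwardModel as delimited text with a JSON geometry header.

    The matrix is stored with 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    header = json.dumps(
        {
            "segment_length": model.grid.length,
            "source_spacing": model.grid.spacing,
            "array_length": model.array.length,
            "electrode_spacing": model.array.spacing,
            "height": model.array.height,
            "normalized": model.normalized,
        }
    )
    with open(path, "w") as fh:
        fh.write("# leakfree-forward-model " + header + "\n")
        np.savetxt(fh, model.L, fmt="%.17g")


def read_forward_model(path) -> ForwardModel:
    """Read a ForwardModel written by :func:`write_forward_model`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# leakfree-forward-model "):
            raise InvalidGeometryError(f"{path} is not a forward-model file")
        meta = json.loads(first[len("# leakfree-forward-model "):])
        L = np.loadtxt(io.StringIO(fh.read()))
    grid = SourceGrid(length=meta["segment_length"], spacing=meta["source_spacing"])
    array = ElectrodeArray(
        length=meta["array_length"],
        spacing=meta["electrode_spacing"],
        height=meta["height"],
    )
    L = np.atleast_2d(L)
    if L.shape != (array.n, grid.p):
        raise InvalidGeometryError(
            f"stored matrix shape {L.shape} does not match header geometry"
        )
    U, D, V = _singular_system(L)
    return ForwardModel(
        grid=grid, array=array, L=L, U=U, D=D, V=V, normalized=bool(meta["normalized"])
    )
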