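"""Uniform cell-centered grids on the unit square.

The segmentation field lives at cell centers of an ``Nx x Ny`` grid covering
``[0,1] x [0,height]`` (height 1 for square images).  Boundary cells carry the
homogeneous Dirichlet condition ``u = 0``; the unknowns of every linear or
nonlinear system are the interior cells, flattened row-major with the x index
fastest, which yields the block-pentadiagonal structure the solvers expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid of ``nx x ny`` cells.

    Parameters
    ----------
    nx, ny : int
        Number of cells per direction; at least 3 so an interior exists.
    height : float
        Physical extent in y.  Defaults to 1 (unit square); ``load_image``
        uses ``ny/nx`` for non-square images so cells stay square.
    """

    nx: int
    ny: int
    height: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if self.height <= 0:
            raise ValueError("height must be positive")

    @property
    def hx(self) -> float:
        return 1.0 / self.nx

    @property
    def hy(self) -> float:
        return self.height / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``: rows are y, columns are x."""
        return (self.ny, self.nx)

    @property
    def n_interior(self) -> int:
        return (self.nx - 2) * (self.ny - 2)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` meshgrid arrays of cell-center coordinates."""
        x = (np.arange(self.nx) + 0.5) * self.hx
        y = (np.arange(self.ny) + 0.5) * self.hy
        return np.meshgrid(x, y)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def pack(self, u: np.ndarray) -> np.ndarray:
        """Flatten the interior of a field to a vector (x fastest)."""
        self._check(u)
        return np.ascontiguousarray(u[1:-1, 1:-1]).ravel()

    def unpack(self, vec: np.ndarray) -> np.ndarray:
        """Embed an interior vector into a full field with zero boundary."""
        if vec.size != self.n_interior:
            raise ValueError(
                f"expected interior vector of size {self.n_interior}, got {vec.size}"
            )
        u = self.zeros()
        u[1:-1, 1:-1] = np.asarray(vec).reshape(self.ny - 2, self.nx - 2)
        return u

    def _check(self, u: np.ndarray) -> None:
        if u.shape != self.shape:
            raise ValueError(f"field shape {u.shape} does not match grid {self.shape}")


def grid_for_image(image: np.ndarray) -> GridSpec:
    """GridSpec matching a 2D image array; non-square images keep square cells."""
    ny, nx = image.shape
    return GridSpec(nx=nx, ny=ny, height=ny / nx if ny != nx else 1.0)
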