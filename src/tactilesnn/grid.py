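"""Mechanoreceptor grid: the discretized patch of skin.

The skin patch is an ``n_rows x n_cols`` lattice of mechanoreceptors at a
fixed pitch (defaults: 80 x 80 sites, 0.15 mm apart, spanning ~12 x 12 mm).
Stimulus templates are defined on a normalized mesh in which each axis runs
from -1 to 1; physical offsets in mm convert at 12 mm per 2 normalized units.
Row 0 is the bottom of the patch (y = -1), column 0 the left edge (x = -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: normalized units per mm (12 mm patch <-> 2 normalized units)
MM_TO_NORM = 2.0 / 12.0


@dataclass(frozen=True)
class MechanoreceptorGrid:
    """Lattice of skin transduction sites.

    Attributes
    ----------
    n_rows, n_cols:
        Lattice dimensions (default 80 x 80).
    pitch_mm:
        Spacing between neighbouring mechanoreceptors in mm.
    """

    n_rows: int = 80
    n_cols: int = 80
    pitch_mm: float = 0.15

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical span (x, y) covered by the lattice, in mm."""
        return (self.pitch_mm * (self.n_cols - 1), self.pitch_mm * (self.n_rows - 1))

    # -- coordinates -------------------------------------------------------

    def mesh_norm(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened normalized coordinates (x, y), each in [-1, 1].

        Site ordering is row-major: index = row * n_cols + col, with row 0
        at the bottom (y = -1) and col 0 at the left (x = -1).
        """
        x = np.linspace(-1.0, 1.0, self.n_cols)
        y = np.linspace(-1.0, 1.0, self.n_rows)
        xx, yy = np.meshgrid(x, y)  # yy varies along rows
        return xx.ravel(), yy.ravel()

    def mesh_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened physical coordinates in mm, origin at the patch centre."""
        x, y = self.mesh_norm()
        return x / MM_TO_NORM, y / MM_TO_NORM

    def site_index(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def site_rowcol(self, index: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        index = np.asarray(index)
        return index // self.n_cols, index % self.n_cols

    def mm_to_norm(self, mm: float | np.ndarray) -> np.ndarray | float:
        return np.asarray(mm) * MM_TO_NORM if np.ndim(mm) else mm * MM_TO_NORM

    def rowcol_to_norm(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Normalized (x, y) of fractional lattice coordinates."""
        x = -1.0 + 2.0 * np.asarray(col, dtype=float) / (self.n_cols - 1)
        y = -1.0 + 2.0 * np.asarray(row, dtype=float) / (self.n_rows - 1)
        return x, y
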