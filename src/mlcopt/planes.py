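"""2D dose planes.

A :class:`DosePlane` is a rectilinear 2D image of absorbed dose (cGy) with
explicit geometry.  The coordinate convention used throughout the package:

* plane coordinates are in millimetres, isocenter at (0, 0);
* leaf motion is along x (columns), y increases upward;
* array row 0 is the **top** row (largest y); ``origin_x``/``origin_y`` give
  the centre of pixel (0, 0), i.e. the top-left pixel;
* pixel (i, j) sits at ``x = origin_x + j*spacing_x``,
  ``y = origin_y - i*spacing_y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DosePlane", "GeometryError", "ValidationError", "DegenerateInputError"]


class ValidationError(ValueError):
    """Invalid values or parameters (NaNs, bad criteria, malformed input)."""


class GeometryError(ValueError):
    """Planes or patterns whose physical geometry is inconsistent."""


class DegenerateInputError(ValueError):
    """Structurally valid input on which no statistic is definable."""


@dataclass
class DosePlane:
    """A 2D absorbed-dose image with geometry.

    Parameters
    ----------
    values : ndarray
        Dose in cGy, shape (rows, cols), at least 2x2, finite and >= 0.
    spacing_x, spacing_y : float
        Pixel pitch in mm (> 0).
    origin_x, origin_y : float
        Position (mm) of the centre of pixel (0, 0); row 0 is the top row.
    depth : float
        Nominal depth of the plane in cm (metadata only).
    """

    values: np.ndarray
    spacing_x: float
    spacing_y: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    depth: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValidationError(
                f"dose plane must be 2D with at least 2x2 pixels, got shape "
                f"{self.values.shape}"
            )
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValidationError(
                f"pixel spacing must be positive, got "
                f"({self.spacing_x}, {self.spacing_y})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dose plane contains NaN or infinite values")
        if np.any(self.values < 0):
            raise ValidationError("dose plane contains negative dose")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x(self) -> np.ndarray:
        """Column coordinates (mm), ascending."""
        return self.origin_x + self.spacing_x * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        """Row coordinates (mm); row 0 is the top (largest y), so descending."""
        return self.origin_y - self.spacing_y * np.arange(self.values.shape[0])

    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of pixel centres, in mm."""
        x = self.x
        y = self.y
        return float(x[0]), float(x[-1]), float(y[-1]), float(y[0])

    def same_grid(self, other: "DosePlane", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing_x - other.spacing_x) <= atol
            and abs(self.spacing_y - other.spacing_y) <= atol
            and abs(self.origin_x - other.origin_x) <= atol
            and abs(self.origin_y - other.origin_y) <= atol
        )

    def copy(self) -> "DosePlane":
        return DosePlane(
            self.values.copy(),
            self.spacing_x,
            self.spacing_y,
            self.origin_x,
            self.origin_y,
            self.depth,
            dict(self.meta),
        )
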