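"""Rotated-ellipse primitives shared by the phantom generator, the line-profile
analysis and the initialization stage.

Coordinate convention: 0-based pixel indices, images indexed ``(row, col)``;
ellipse centers are given as ``(cx, cy)`` in (col, row) order to match the
usual image (x, y) reading, with y increasing downwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Ellipse"]


@dataclass(frozen=True)
class Ellipse:
    """An ellipse with center ``(cx, cy)`` px, semi-axes ``a, b`` px and
    rotation ``theta`` (radians, counter-clockwise in (x, y))."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got a={self.a}, b={self.b}")

    def scaled(self, factor: float) -> "Ellipse":
        return replace(self, a=self.a * factor, b=self.b * factor)

    def quad_form(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate u²/a² + v²/b² in the ellipse frame; ≤ 1 inside."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.a) ** 2 + (v / self.b) ** 2

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.quad_form(x, y) <= 1.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixel centers inside the ellipse, shape (rows, cols)."""
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        return self.contains(xx, yy)

    def point_at(self, phi: float) -> tuple[float, float]:
        """Boundary point at parametric angle ``phi`` (ellipse frame)."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = self.a * math.cos(phi)
        v = self.b * math.sin(phi)
        return (self.cx + c * u - s * v, self.cy + s * u + c * v)

    def boundary_point_toward(self, direction: float) -> tuple[float, float]:
        """Intersection of the ray from the center at image-frame angle
        ``direction`` (radians, y down) with the ellipse boundary."""
        dx, dy = math.cos(direction), math.sin(direction)
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        t = 1.0 / math.sqrt((u / self.a) ** 2 + (v / self.b) ** 2)
        return (self.cx + t * dx, self.cy + t * dy)

    def line_intersections(self, orientation: str, position: float) -> list[tuple[float, float]]:
        """Analytic intersections of a pixel row/column line with the ellipse.

        ``orientation`` is ``"horizontal"`` (line y = position, unknown x) or
        ``"vertical"`` (line x = position, unknown y). Returns 0, 1 or 2
        ``(x, y)`` points sorted along the line.
        """
        c, s = math.cos(self.theta), math.sin(self.theta)
        if orientation == "horizontal":
            k = position - self.cy
            # u = c·X + s·k, v = -s·X + c·k with X = x - cx
            A = (c / self.a) ** 2 + (s / self.b) ** 2
            B = 2.0 * k * (c * s / self.a**2 - s * c / self.b**2)
            C = (s * k / self.a) ** 2 + (c * k / self.b) ** 2 - 1.0
        elif orientation == "vertical":
            k = position - self.cx
            # u = c·k + s·Y, v = -s·k + c·Y with Y = y - cy
            A = (s / self.a) ** 2 + (c / self.b) ** 2
            B = 2.0 * k * (c * s / self.a**2 - s * c / self.b**2)
            C = (c * k / self.a) ** 2 + (s * k / self.b) ** 2 - 1.0
        else:
            raise ValueError(f"orientation must be 'horizontal' or 'vertical', got {orientation!r}")
        disc = B * B - 4.0 * A * C
        if disc < 0:
            return []
        roots = sorted({(-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)})
        if orientation == "horizontal":
            return [(self.cx + r, float(position)) for r in roots]
        return [(float(position), self.cy + r) for r in roots]

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipse":
        return cls(**d)
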