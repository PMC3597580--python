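"""Planar affine transforms and their decomposition.

The transform maps moving-frame coordinates onto fixed-frame coordinates:

    (x, y)  ->  (a11*x + a12*y + tx,  a21*x + a22*y + ty)

Coordinates follow the image convention used throughout the package:
0-based, x = column, y = row, origin at the top-left corner. A positive
rotation therefore turns the +x axis toward the +y axis, i.e. clockwise
when the image is displayed with y pointing down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidTransformError

_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class TransformDecomposition:
    """Rotation / shear / scale / translation readout of an affine map.

    The linear part factors uniquely as  R(rotation) @ Shear @ Scale  with
    Shear = [[1, shear], [0, 1]] and Scale = diag(scale_x, scale_y); the
    translation is carried over unchanged. ``recompose`` reproduces the
    original transform to machine precision.
    """

    scale_x: float
    scale_y: float
    rotation: float  # degrees
    shear: float
    translation: tuple[float, float]

    def recompose(self) -> "AffineTransform":
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        rot = np.array([[c, -s], [s, c]])
        sh = np.array([[1.0, self.shear], [0.0, 1.0]])
        sc = np.diag([self.scale_x, self.scale_y])
        lin = rot @ sh @ sc
        return AffineTransform(
            lin[0, 0], lin[0, 1], lin[1, 0], lin[1, 1],
            self.translation[0], self.translation[1],
        )


@dataclass(frozen=True)
class AffineTransform:
    """Six-parameter planar affine map (2x2 linear part plus translation)."""

    a11: float
    a12: float
    a21: float
    a22: float
    tx: float
    ty: float

    # -- constructors -------------------------------------------------

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, float(dx), float(dy))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        """Build from a 2x3 or 3x3 matrix (row-major, [x'; y'] = A [x; y; 1])."""
        m = np.asarray(m, dtype=float)
        if m.shape == (3, 3):
            m = m[:2, :]
        if m.shape != (2, 3):
            raise InvalidTransformError(f"expected 2x3 or 3x3 matrix, got {m.shape}")
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2])

    @classmethod
    def from_params(
        cls,
        scale: float | tuple[float, float] = 1.0,
        rotation: float = 0.0,
        shear: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Compose rotation(deg) . shear . scale about ``center``, then translate."""
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        lin = TransformDecomposition(
            sx, sy, rotation, shear, (0.0, 0.0)
        ).recompose().linear
        cx, cy = center
        c = np.array([cx, cy])
        t = c - lin @ c + np.asarray(translation, dtype=float)
        return cls(lin[0, 0], lin[0, 1], lin[1, 0], lin[1, 1], t[0], t[1])

    # -- basic algebra ------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix."""
        return np.array(
            [
                [self.a11, self.a12, self.tx],
                [self.a21, self.a22, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def determinant(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    def _check_invertible(self) -> None:
        scale2 = max(abs(self.a11), abs(self.a12), abs(self.a21), abs(self.a22), 1.0) ** 2
        if abs(self.determinant) <= _SINGULAR_TOL * scale2:
            raise InvalidTransformError(f"singular transform (det={self.determinant:g})")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.linear.T + self.offset
        return out[0] if single else out

    __call__ = apply

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self . other (apply ``other`` first)."""
        m = self.matrix() @ other.matrix()
        return AffineTransform.from_matrix(m)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def invert(self) -> "AffineTransform":
        self._check_invertible()
        lin_inv = np.linalg.inv(self.linear)
        t_inv = -lin_inv @ self.offset
        return AffineTransform(
            lin_inv[0, 0], lin_inv[0, 1], lin_inv[1, 0], lin_inv[1, 1],
            t_inv[0], t_inv[1],
        )

    def decompose(self) -> TransformDecomposition:
        """Unique rotation . shear . scale (+ translation) factorization."""
        self._check_invertible()
        # Choose the rotation that zeroes the (1,0) entry of R^T A; the
        # remainder K = R^T A is upper triangular: K = Shear @ Scale.
        theta = math.atan2(self.a21, self.a11)
        c, s = math.cos(theta), math.sin(theta)
        rot_t = np.array([[c, s], [-s, c]])
        k = rot_t @ self.linear
        sx = k[0, 0]
        sy = k[1, 1]
        if sx < 0:  # fold a 180-degree flip into the rotation instead
            theta += math.pi if theta <= 0 else -math.pi
            c, s = math.cos(theta), math.sin(theta)
            k = np.array([[c, s], [-s, c]]) @ self.linear
            sx, sy = k[0, 0], k[1, 1]
        shear = k[0, 1] / sy
        return TransformDecomposition(
            scale_x=float(sx),
            scale_y=float(sy),
            rotation=math.degrees(theta),
            shear=float(shear),
            translation=(self.tx, self.ty),
        )

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = self.decompose()
        return {
            "matrix": [
                [self.a11, self.a12, self.tx],
                [self.a21, self.a22, self.ty],
            ],
            "decomposition": {
                "scale_x": d.scale_x,
                "scale_y": d.scale_y,
                "rotation_deg": d.rotation,
                "shear": d.shear,
                "translation": list(d.translation),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls.from_matrix(np.asarray(d["matrix"], dtype=float))
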