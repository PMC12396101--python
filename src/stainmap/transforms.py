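"""2D rigid transforms for section-to-section registration.

Coordinates are (row, col) pixel positions. A transform maps points of the
*moving* section into the *fixed* frame:

    p' = R(theta) @ (p - c) + c + t

with rotation ``theta`` in degrees (counter-clockwise in (row, col) axes),
rotation center ``c`` and translation ``t = (drow, dcol)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform2D:
    rotation_deg: float
    translation: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)

    # -- linear form ---------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    @property
    def offset(self) -> np.ndarray:
        c = np.asarray(self.center, float)
        t = np.asarray(self.translation, float)
        return c - self.matrix @ c + t

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, (0.0, 0.0))

    @classmethod
    def from_matrix_offset(cls, matrix: np.ndarray, offset: np.ndarray,
                           center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform2D":
        ang = np.rad2deg(np.arctan2(matrix[1, 0], matrix[0, 0]))
        c = np.asarray(center, float)
        # offset = c - R c + t  =>  t = offset - c + R c
        t = np.asarray(offset, float) - c + matrix @ c
        return cls(float(ang), (float(t[0]), float(t[1])), (float(c[0]), float(c[1])))

    # -- algebra -------------------------------------------------------
    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Return self o first (apply ``first``, then ``self``)."""
        a = self.matrix @ first.matrix
        b = self.matrix @ first.offset + self.offset
        return RigidTransform2D.from_matrix_offset(a, b, self.center)

    def inverse(self) -> "RigidTransform2D":
        a = self.matrix.T
        b = -a @ self.offset
        return RigidTransform2D.from_matrix_offset(a, b, self.center)

    # -- application ---------------------------------------------------
    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.offset

    def apply_to_image(self, image: np.ndarray, order: int = 1,
                       cval: float = 0.0) -> np.ndarray:
        """Resample ``image`` into the fixed frame (output shape = input shape)."""
        if abs(self.rotation_deg) < 1e-12 and np.allclose(self.translation, 0.0):
            return image.copy()
        inv = self.inverse()
        out = ndimage.affine_transform(
            np.asarray(image, float), inv.matrix, offset=inv.offset,
            order=order, mode="constant", cval=cval)
        if image.dtype == bool:
            return out > 0.5
        return out

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(self.rotation_deg) <= tol and max(map(abs, self.translation)) <= tol

    def to_dict(self) -> dict:
        return {"rotation_deg": self.rotation_deg,
                "translation": list(self.translation),
                "center": list(self.center)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(d["rotation_deg"], tuple(d["translation"]), tuple(d["center"]))


def transform_residual(recovered: RigidTransform2D, truth: RigidTransform2D,
                       points: np.ndarray) -> tuple[float, float]:
    """Residual between two transforms: (|rotation error| deg, max point displacement px).

    Compares the *mappings* (parameterizations may use different centers) by
    composing ``recovered o truth^-1`` and measuring its action on ``points``.
    """
    resid = recovered.compose(truth.inverse())
    ang = abs(((resid.rotation_deg + 180.0) % 360.0) - 180.0)
    moved = resid.apply_to_points(points)
    disp = float(np.max(np.linalg.norm(moved - np.atleast_2d(points), axis=1)))
    return float(ang), disp
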