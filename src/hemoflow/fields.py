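"""Cell-centred tensor and vector field containers.

Fields live on the cells of a :class:`~hemoflow.mesh.StructuredGrid`.
Vectors are plain ``(n, 2)`` arrays (axial ``x``, transverse/radial ``y``).
Tensors carry the planar 2x2 components plus, in axisymmetric mode, the
explicit hoop (theta-theta) component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Per-cell 2-component vectors: shape (ncell, 2), columns (x, y).
VectorField2D = np.ndarray


@dataclass
class TensorField2D:
    """Per-cell 2x2 (plus optional hoop) tensor field.

    ``yx is None`` marks a symmetric tensor (``yx == xy`` implicitly).
    ``tt`` is the hoop component, present in axisymmetric mode for the
    symmetric parts of velocity gradients (D_tt = v_r / r) and stresses.
    """

    xx: np.ndarray
    xy: np.ndarray
    yy: np.ndarray
    yx: np.ndarray | None = None
    tt: np.ndarray | None = None

    @property
    def is_symmetric(self) -> bool:
        return self.yx is None

    def get_yx(self) -> np.ndarray:
        return self.xy if self.yx is None else self.yx

    def trace(self) -> np.ndarray:
        t = self.xx + self.yy
        if self.tt is not None:
            t = t + self.tt
        return t

    def dot_vec(self, v: VectorField2D) -> VectorField2D:
        """Tensor-vector (matrix @ vector) product per cell."""
        yx = self.get_yx()
        out = np.empty((self.xx.shape[0], 2))
        out[:, 0] = self.xx * v[:, 0] + self.xy * v[:, 1]
        out[:, 1] = yx * v[:, 0] + self.yy * v[:, 1]
        return out

    @classmethod
    def zeros(cls, n: int, *, symmetric: bool = True, hoop: bool = False) -> "TensorField2D":
        z = lambda: np.zeros(n)  # noqa: E731
        return cls(
            xx=z(), xy=z(), yy=z(),
            yx=None if symmetric else z(),
            tt=z() if hoop else None,
        )

    def assert_antisymmetric(self, tol: float = 1e-9) -> None:
        """Raise if the field is not a spin tensor (W = -W^T) within ``tol``.

        ``tol`` is relative to the largest off-diagonal magnitude.
        """
        yx = self.get_yx()
        scale = max(float(np.max(np.abs(self.xy)) if self.xy.size else 0.0), 1e-300)
        bad = (
            np.max(np.abs(self.xx)) > tol * scale
            or np.max(np.abs(self.yy)) > tol * scale
            or np.max(np.abs(self.xy + yx)) > tol * scale
        )
        if self.tt is not None and np.max(np.abs(self.tt)) > tol * scale:
            bad = True
        if bad:
            raise ValueError("tensor field is not antisymmetric within tolerance")
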