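"""Shape scores and principal-axis estimation for lymph nodes.

Two scalar shape descriptors are computed from the three principal
diameters (a <= b <= c, mm):

* ``ratio_2d`` — a/c, the short-to-long diameter ratio a reader would
  measure on a single planar image.
* ``sphericity`` — 2·∛(abc/8)/c = ∛(abc)/c, the diameter of the sphere
  with the node's ellipsoid volume divided by the longest diameter.
  1 for a perfect sphere, smaller for elongated (oval) nodes.

Metastatic nodes tend toward spherical, benign nodes toward oblong, so
both scores increase with suspicion of metastasis; sphericity uses all
three diameters and always dominates the planar ratio
(ratio_2d <= sphericity <= 1, equal iff a = b = c).

``estimate_axes`` recovers the diameters from a binary segmentation
mask via the second moments of the voxel cloud: a solid uniform
ellipsoid with semi-axis r along a principal direction has variance
r²/5 along it, so the eigenvalues λ of the mm-scaled coordinate
covariance give diameters 2·sqrt(5·λ). The estimator is rotation
invariant and exact for ellipsoids up to discretization.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence, Union

import numpy as np
import pandas as pd

from nodesphere.types import AxisTriple

logger = logging.getLogger(__name__)

AxesLike = Union[AxisTriple, Sequence[float]]

#: Below this many voxels the moment estimate is flagged as degraded.
MIN_RELIABLE_VOXELS = 50


def _as_triple(axes: AxesLike) -> AxisTriple:
    if isinstance(axes, AxisTriple):
        return axes
    return AxisTriple(*(float(v) for v in axes))


def ratio_2d(axes: AxesLike) -> float:
    """Short-to-long diameter ratio a/c, in (0, 1]."""
    t = _as_triple(axes)
    return t.a / t.c


def sphericity(axes: AxesLike) -> float:
    """Equal-volume-sphere diameter over longest diameter, ∛(abc)/c.

    The divisor 8 in the diameter form 2·∛(abc/8)/c converts the full
    diameters to semi-axes; algebraically the score is ∛(abc)/c.
    """
    t = _as_triple(axes)
    return float(np.cbrt(t.a * t.b * t.c) / t.c)


def score_nodes(nodes: pd.DataFrame) -> pd.DataFrame:
    """Append ``ratio_2d`` and ``sphericity`` columns to a node table.

    Expects the axis columns ``a_mm, b_mm, c_mm``; rows are assumed
    already canonicalized (a <= b <= c), as the readers guarantee.
    """
    for col in ("a_mm", "b_mm", "c_mm"):
        if col not in nodes.columns:
            raise ValueError(f"node table lacks required column {col!r}")
    out = nodes.copy()
    a = out["a_mm"].to_numpy(dtype=float)
    b = out["b_mm"].to_numpy(dtype=float)
    c = out["c_mm"].to_numpy(dtype=float)
    if np.any(a <= 0) or np.any(a > b) or np.any(b > c):
        raise ValueError("axis columns must satisfy 0 < a <= b <= c per row")
    out["ratio_2d"] = a / c
    out["sphericity"] = np.cbrt(a * b * c) / c
    return out


def estimate_axes(
    mask: np.ndarray,
    voxel_mm: Sequence[float],
    min_voxels: int = MIN_RELIABLE_VOXELS,
) -> AxisTriple:
    """Estimate the three principal diameters of a binary mask, mm.

    Parameters
    ----------
    mask
        3D boolean/integer array; nonzero voxels form the object.
    voxel_mm
        Voxel spacing along each array axis, mm.
    min_voxels
        Below this object size a degraded-precision warning is emitted
        (the moment estimate is noisy on tiny objects).

    Returns
    -------
    AxisTriple
        Diameters 2·sqrt(5·λ) from the eigenvalues of the mm-scaled
        coordinate covariance, sorted ascending.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got {mask.ndim}D")
    spacing = np.asarray(voxel_mm, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("voxel_mm must be three positive spacings")
    coords = np.argwhere(mask)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty mask: no voxels set")
    if n < min_voxels:
        warnings.warn(
            f"object has only {n} voxels (<{min_voxels}); "
            "axis estimate is degraded",
            stacklevel=2,
        )
    mm = coords * spacing  # (n, 3), mm
    cov = np.cov(mm.T, bias=True) if n > 1 else np.zeros((3, 3))
    lam = np.linalg.eigvalsh(np.atleast_2d(cov))
    lam = np.clip(lam, 0.0, None)
    diameters = 2.0 * np.sqrt(5.0 * lam)
    return AxisTriple.from_sorted(diameters)
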