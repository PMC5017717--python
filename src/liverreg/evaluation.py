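"""Registration accuracy metrics: Dice, mean surface distance, landmark error.

* DSC(X, Y) = 2 |X n Y| / (|X| + |Y|) by voxel counting.
* MSD(X, Y): surfaces are each mask minus its one-voxel erosion
  (6-connected by default); the metric is the symmetric mean of the closest
  Euclidean distances (world mm, voxel centers, exact distance transform)
  from each surface voxel of one mask to the other surface, normalized by
  the total surface voxel count.
* MCD(A, B; T) = mean_i |a_i - T(b_i)| over paired landmarks, with T the
  estimated transform from the fixed image (B's frame) into the moving
  image (A's frame) — a target registration error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._exceptions import (ConfigurationError, ContractViolationError,
                          EmptyInputError)
from .image_core import BinaryMask, PointSetMM


@dataclass
class EvaluationReport:
    """Metrics for one registered case."""

    dsc: float
    msd_mm: float
    mcd_mm: float | None = None
    per_landmark_mm: list = field(default_factory=list)
    success: bool | None = None

    @property
    def n_landmarks(self):
        return len(self.per_landmark_mm)

    def to_dict(self):
        return {"dsc": self.dsc, "msd_mm": self.msd_mm,
                "mcd_mm": self.mcd_mm,
                "n_landmarks": self.n_landmarks,
                "per_landmark_mm": list(self.per_landmark_mm),
                "success": self.success}

    def to_json(self, indent=2):
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self):
        lines = [f"DSC\t{self.dsc:.4f}", f"MSD_mm\t{self.msd_mm:.4f}"]
        if self.mcd_mm is not None:
            lines.append(f"MCD_mm\t{self.mcd_mm:.4f}")
            lines.append(f"n_landmarks\t{self.n_landmarks}")
        if self.success is not None:
            lines.append(f"success\t{int(self.success)}")
        return "\n".join(lines) + "\n"


def _check_geometry(X: BinaryMask, Y: BinaryMask):
    if not X.geometry.same_as(Y.geometry):
        raise ContractViolationError("masks must share the same geometry")


def dice(X: BinaryMask, Y: BinaryMask) -> float:
    """Dice similarity coefficient 2|XnY| / (|X| + |Y|)."""
    _check_geometry(X, Y)
    x = np.asarray(X.voxels, bool)
    y = np.asarray(Y.voxels, bool)
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        raise EmptyInputError("both masks are empty")
    return 2.0 * int((x & y).sum()) / (nx + ny)


def extract_surface(mask: BinaryMask, connectivity: int = 1) -> np.ndarray:
    """Boolean surface: mask minus its one-voxel erosion.

    ``connectivity=1`` is the 6-connected structuring element (default),
    ``connectivity=3`` the full 26-connected cube. Voxels on the volume
    border count as surface (the outside is treated as background).
    """
    m = np.asarray(mask.voxels, bool)
    if not m.any():
        raise EmptyInputError("cannot extract the surface of an empty mask")
    if connectivity not in (1, 2, 3):
        raise ConfigurationError("connectivity must be 1, 2 or 3")
    struct = ndimage.generate_binary_structure(3, connectivity)
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~eroded


def mean_surface_distance(X: BinaryMask, Y: BinaryMask,
                          connectivity: int = 1) -> float:
    """Symmetric mean closest surface-to-surface distance in mm."""
    _check_geometry(X, Y)
    sx = extract_surface(X, connectivity)
    sy = extract_surface(Y, connectivity)
    spacing = X.spacing
    # exact Euclidean distance (voxel centers, anisotropic world spacing)
    d_to_y = ndimage.distance_transform_edt(~sy, sampling=spacing)
    d_to_x = ndimage.distance_transform_edt(~sx, sampling=spacing)
    n_x, n_y = int(sx.sum()), int(sy.sum())
    total = d_to_y[sx].sum() + d_to_x[sy].sum()
    return float(total / (n_x + n_y))


def mean_corresponding_distance(A_points: PointSetMM, B_points: PointSetMM,
                                T=None):
    """(MCD mm, per-pair distances): mean |a_i - T(b_i)| over landmark pairs."""
    a = A_points.points
    b = B_points.points
    if len(a) != len(b) or len(a) < 1:
        raise ContractViolationError(
            f"landmark counts differ or empty ({len(a)} vs {len(b)})")
    tb = T.apply(b) if T is not None else b
    d = np.linalg.norm(a - tb, axis=1)
    return float(d.mean()), d


def evaluate_masks(X: BinaryMask, Y: BinaryMask,
                   A_points: PointSetMM | None = None,
                   B_points: PointSetMM | None = None, T=None,
                   connectivity: int = 1) -> EvaluationReport:
    """Assemble a full report (DSC + MSD, MCD when landmarks are given)."""
    d = dice(X, Y)
    msd = mean_surface_distance(X, Y, connectivity)
    mcd, per = (None, [])
    if A_points is not None and B_points is not None:
        mcd, dist = mean_corresponding_distance(A_points, B_points, T)
        per = dist.tolist()
    return EvaluationReport(d, msd, mcd, per)
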