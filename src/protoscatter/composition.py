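"""Material decomposition of a treatment field.

The analysis region is either the 50% isodose region of a computed dose
distribution (the clinical convention: voxels receiving at least half the
maximum dose) or the beam's-eye-view (BEV) cylinder; the HU values inside
it are histogrammed and grouped into the five material classes, giving the
percentage composition used by the empirical scatter-factor models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlanError, InsufficientDataError, InvalidInputError
from .materials import MaterialClass, classify_hu_array
from .phantoms import HUGrid


@dataclass(frozen=True)
class CompositionBreakdown:
    """Fractions (0-1) of the five material classes in a region."""

    air: float
    thin_tissue: float
    soft_tissue: float
    bone: float
    dense_bone: float

    def __post_init__(self) -> None:
        fracs = self.as_array()
        if (fracs < 0).any() or (fracs > 1).any():
            raise InvalidInputError("fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise InvalidInputError("fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.air, self.thin_tissue, self.soft_tissue, self.bone, self.dense_bone]
        )

    @property
    def air_pct(self) -> float:
        return 100.0 * self.air

    @property
    def dense_bone_pct(self) -> float:
        return 100.0 * self.dense_bone

    def to_dict(self) -> dict:
        return {c.value: float(f) for c, f in zip(MaterialClass, self.as_array())}


def isodose_mask(dose: np.ndarray, fraction: float) -> np.ndarray:
    """Voxels receiving at least ``fraction`` of the maximum dose
    (inclusive threshold); ``fraction`` 0.5 is the clinical 50% region."""
    dose = np.asarray(dose, float)
    if not (0.0 <= fraction <= 1.0):
        raise InvalidInputError("isodose fraction must be in [0, 1]")
    dmax = dose.max() if dose.size else 0.0
    if dmax <= 0:
        raise DegeneratePlanError("dose distribution has no positive maximum")
    if fraction == 0.0:
        return dose > 0
    return dose >= fraction * dmax


def composition_breakdown(grid: HUGrid, mask: np.ndarray) -> CompositionBreakdown:
    """Five-class composition of the masked voxels (unweighted counts)."""
    mask = np.asarray(mask, bool)
    if mask.shape != grid.shape:
        raise InvalidInputError("mask shape does not match grid")
    n = int(mask.sum())
    if n == 0:
        raise InsufficientDataError("empty composition mask")
    cls = classify_hu_array(grid.values[mask])
    counts = np.bincount(cls, minlength=5)
    fr = counts / n
    return CompositionBreakdown(*[float(f) for f in fr])


def hu_histogram(grid: HUGrid, mask: np.ndarray, bin_width: int = 10) -> pd.DataFrame:
    """HU histogram of a region as a DataFrame with columns ``hu, count``
    (bin lower edges); the raw material of the composition figures."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise InsufficientDataError("empty histogram mask")
    hu = grid.values[mask].astype(int)
    lo = (hu.min() // bin_width) * bin_width
    hi = ((hu.max() // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(hu, bins=edges)
    return pd.DataFrame({"hu": edges[:-1], "count": counts})
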