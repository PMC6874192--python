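"""Hounsfield-unit material model.

CT numbers are mapped in two independent ways:

* a coarse five-class segmentation (air, thin tissue, soft tissue, bone,
  dense bone) used for field-composition histograms, and
* a piecewise-linear calibration from HU to relative proton stopping power
  (RSP), mass density, and inverse scattering length, in the spirit of the
  stoichiometric CT calibrations used clinically.

The five classes partition the integer HU interval [-1000, 1245] at edges
-1000, -650, -500, 125, 500, 1245; the upper edge of each class is
inclusive. HU below -1000 clamps to air, above 1245 to dense bone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

HU_MIN = -1024
HU_MAX = 3000

#: Class bin upper edges (inclusive), in HU, after clamping to [-1000, 1245].
_CLASS_EDGES = (-650, -500, 125, 500, 1245)

#: Radiation length of water in cm, used to convert accumulated
#: inverse-scattering-length path into x/X0.
X0_WATER_CM = 36.08


class MaterialClass(enum.Enum):
    """The five HU-binned material classes."""

    AIR = "air"
    THIN_TISSUE = "thin_tissue"
    SOFT_TISSUE = "soft_tissue"
    BONE = "bone"
    DENSE_BONE = "dense_bone"


_CLASS_ORDER = (
    MaterialClass.AIR,
    MaterialClass.THIN_TISSUE,
    MaterialClass.SOFT_TISSUE,
    MaterialClass.BONE,
    MaterialClass.DENSE_BONE,
)


@dataclass(frozen=True)
class MaterialProperties:
    """Interpolated material properties at one HU value.

    rsp
        proton stopping power relative to water (water = 1).
    density
        mass density in g/cm^3.
    inverse_scattering_length
        1/X0 relative to water (water = 1); larger means the material
        deflects protons more strongly per unit path.
    """

    rsp: float
    density: float
    inverse_scattering_length: float

    def __post_init__(self) -> None:
        if self.rsp < 0 or self.density < 0 or self.inverse_scattering_length < 0:
            raise InvalidInputError("material properties must be non-negative")


def classify_hu(hu) -> MaterialClass:
    """Classify an integer HU value into one of the five material classes.

    Values in [-1024, -1000) clamp to air; values in (1245, 3000] map to
    dense bone. Inputs outside [-1024, 3000] or non-integral inputs raise
    :class:`InvalidInputError`.
    """
    if isinstance(hu, (bool, str)) or not float(hu).is_integer():
        raise InvalidInputError(f"HU must be an integer, got {hu!r}")
    hu = int(hu)
    if hu < HU_MIN or hu > HU_MAX:
        raise InvalidInputError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
    hu = min(max(hu, -1000), 1245)
    for edge, cls in zip(_CLASS_EDGES, _CLASS_ORDER):
        if hu <= edge:
            return cls
    return MaterialClass.DENSE_BONE


def classify_hu_array(hu: np.ndarray) -> np.ndarray:
    """Vectorised classification; returns an integer array of class indices
    following the order air, thin_tissue, soft_tissue, bone, dense_bone."""
    hu = np.clip(np.asarray(hu), -1000, 1245)
    return np.searchsorted(np.asarray(_CLASS_EDGES), hu, side="left")


def class_representative_hu(cls: MaterialClass) -> int:
    """Midpoint HU of a class bin (used as a canonical example voxel)."""
    edges = (-1000,) + _CLASS_EDGES
    i = _CLASS_ORDER.index(cls)
    lo = edges[i] + (1 if i > 0 else 0)
    hi = edges[i + 1]
    return int((lo + hi) // 2)


@dataclass
class RspCalibration:
    """Piecewise-linear HU calibration.

    ``knots`` is a DataFrame with columns ``hu, rsp, density, inv_x0``; HU
    knots must be strictly increasing and span at least [-1000, 1245].
    Evaluation clamps HU outside the knot range to the end knots.
    """

    knots: pd.DataFrame
    _luts: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"hu", "rsp", "density", "inv_x0"}
        if self.knots is None or len(self.knots) == 0:
            raise ConfigurationError("empty calibration")
        if not required.issubset(self.knots.columns):
            raise ConfigurationError(f"calibration needs columns {sorted(required)}")
        hu = self.knots["hu"].to_numpy(float)
        if len(hu) < 2 or not np.all(np.diff(hu) > 0):
            raise ConfigurationError("calibration HU knots must be strictly increasing")
        if hu[0] > -1000 or hu[-1] < 1245:
            raise ConfigurationError("calibration must cover [-1000, 1245] HU")
        for col in ("rsp", "density", "inv_x0"):
            if (self.knots[col].to_numpy(float) < 0).any():
                raise ConfigurationError(f"negative {col} in calibration")

    def _lut(self, col: str) -> np.ndarray:
        # Dense lookup table over the full clamped HU range; interpolation
        # is exact at the integer knots.
        if col not in self._luts:
            hu_axis = np.arange(HU_MIN, HU_MAX + 1, dtype=float)
            self._luts[col] = np.interp(
                hu_axis, self.knots["hu"].to_numpy(float), self.knots[col].to_numpy(float)
            )
        return self._luts[col]

    def rsp(self, hu) -> np.ndarray | float:
        return self._eval("rsp", hu)

    def density(self, hu) -> np.ndarray | float:
        return self._eval("density", hu)

    def inv_x0(self, hu) -> np.ndarray | float:
        return self._eval("inv_x0", hu)

    def _eval(self, col: str, hu):
        lut = self._lut(col)
        idx = np.clip(np.asarray(hu, dtype=np.int64) - HU_MIN, 0, HU_MAX - HU_MIN)
        out = lut[idx]
        return float(out) if np.isscalar(hu) or np.ndim(hu) == 0 else out


def material_properties(hu, cal: RspCalibration) -> MaterialProperties:
    """Interpolate RSP, density, and inverse scattering length at one HU."""
    if isinstance(hu, (bool, str)) or not float(hu).is_integer():
        raise InvalidInputError(f"HU must be an integer, got {hu!r}")
    hu = int(hu)
    if hu < HU_MIN or hu > HU_MAX:
        raise InvalidInputError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
    return MaterialProperties(
        rsp=float(cal.rsp(hu)),
        density=float(cal.density(hu)),
        inverse_scattering_length=float(cal.inv_x0(hu)),
    )


def load_calibration_csv(path) -> RspCalibration:
    """Read a calibration from CSV with header ``hu,rsp,density,inv_x0``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough
        raise ConfigurationError(f"cannot read calibration {path}: {exc}") from exc
    return RspCalibration(df)


def default_calibration() -> RspCalibration:
    """The calibration shipped with the package.

    Seven knots reproduce the qualitative air/water/bone ordering of
    clinical stoichiometric calibrations without embedding full tissue
    tables; the inverse scattering length is density times a class factor
    (1.0 for air and tissue, 1.7 for bone) reflecting the higher effective
    Z of calcified tissue.
    """
    ref = resources.files("protoscatter").joinpath("data/default_calibration.csv")
    with resources.as_file(ref) as p:
        return load_calibration_csv(Path(p))
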