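"""Empirical single-predictor scatter-factor models.

Across treatment fields the patient scatter factor falls roughly linearly
with the percentage of air in the field and rises with the percentage of
dense bone, while the compensator scatter factor rises linearly with the
thickness IQR. These relationships are shipped as *fitted data objects*
produced from pipeline runs (the literature's own coefficients are not
embedded); a fit can also be entered by hand from published values.

The single-predictor models are only valid when one heterogeneity type
dominates: prediction refuses (overridably) when a field has both more
than 5% air and more than 2% dense bone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import InvalidInputError, MixedFieldError

PREDICTORS = ("air_pct", "dense_bone_pct", "iqr_cm")


@dataclass(frozen=True)
class LinearFit:
    """An ordinary-least-squares line factor = intercept + slope * x."""

    slope: float
    intercept: float
    r2: float
    n: int
    predictor_name: str
    x_range: tuple[float, float] = (float("-inf"), float("inf"))

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError("fit needs n >= 2")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise InvalidInputError("r2 must be in [0, 1]")
        if self.predictor_name not in PREDICTORS:
            raise InvalidInputError(f"predictor must be one of {PREDICTORS}")

    def to_json(self) -> str:
        d = asdict(self)
        d["predictor"] = d.pop("predictor_name")
        d["x_range"] = list(d["x_range"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearFit":
        d = json.loads(text)
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r2=d.get("r2", 1.0),
            n=d.get("n", 2),
            predictor_name=d.get("predictor", d.get("predictor_name")),
            x_range=tuple(d.get("x_range", (float("-inf"), float("inf")))),
        )


def fit_line(xs, ys, predictor_name: str = "air_pct") -> LinearFit:
    """Ordinary least squares of factor against a single predictor."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InvalidInputError("xs and ys must be 1-D and equal length")
    if xs.size < 2:
        raise InvalidInputError("need at least two points")
    if np.allclose(xs, xs[0]):
        raise InvalidInputError("singular fit: all x values equal")
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # all residuals zero on a vertical spread, etc.
        r2 = 1.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(max(r2, 0.0), 1.0),
        n=int(xs.size),
        predictor_name=predictor_name,
        x_range=(float(xs.min()), float(xs.max())),
    )


def fit_standard_error(xs, ys) -> float:
    """Standard error of the OLS slope (for parameter-recovery checks)."""
    res = stats.linregress(np.asarray(xs, float), np.asarray(ys, float))
    return float(res.stderr)


def predict(fit: LinearFit, x: float, air_pct: float | None = None,
            dense_bone_pct: float | None = None,
            allow_mixed: bool = False) -> float:
    """Evaluate a fitted factor model at predictor value ``x``.

    Extrapolation beyond 1.5x the fitted x-range raises a warning. When
    the field composition is supplied and shows both appreciable air
    (> 5%) and dense bone (> 2%), prediction raises
    :class:`MixedFieldError` unless ``allow_mixed`` — a single-predictor
    model cannot represent the two competing effects.
    """
    if (
        not allow_mixed
        and air_pct is not None
        and dense_bone_pct is not None
        and air_pct > 5.0
        and dense_bone_pct > 2.0
    ):
        raise MixedFieldError(
            f"field has {air_pct:.1f}% air and {dense_bone_pct:.1f}% dense bone; "
            "single-predictor model not applicable"
        )
    lo, hi = fit.x_range
    if np.isfinite(lo) and np.isfinite(hi):
        span = hi - lo
        if span > 0 and (x < lo - 0.25 * span or x > hi + 0.25 * span):
            warnings.warn(
                f"predictor value {x} extrapolates beyond 1.5x the fitted "
                f"range [{lo}, {hi}]",
                stacklevel=2,
            )
    return fit.intercept + fit.slope * float(x)
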