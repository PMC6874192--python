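"""Published scatter-factor study tables and their agreement statistics.

Two fixtures ship with the package: twelve fields with both Monte Carlo
(MC) and pencil-beam (TPS) factors for four treatment sites, and
twenty-six pencil-beam factor triples (CSF, PSF, CPSF) for individual
patient plans. The statistics implemented here are the ones quoted when
comparing the two calculation techniques: mean and maximum absolute
differences in percentage points, per-site means, factor ranges, and the
CPSF product check.

The "difference" convention is absolute percentage points of the factor,
|a - b| * 100, not relative percent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import FixtureError, InvalidInputError

SITES = ("brain", "pancreas", "prostate", "lung")

_CHECKSUMS = {
    "table1": "aead420c9c99ac4911597dcaad1e8ebac4040bcc62891885838e21f9eeb35303",
    "table2": "26a6db2032d39ceab638fcd4e7b3d648efa7d3c2e5c322e34ba15e5f57a25b38",
}


@dataclass(frozen=True)
class FieldRecord:
    """One field with factors from both calculation techniques."""

    site: str
    field_id: int
    tps_csf: float
    mc_csf: float
    tps_psf: float
    mc_psf: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise InvalidInputError(f"unknown site {self.site!r}")
        for v in (self.tps_csf, self.mc_csf, self.tps_psf, self.mc_psf):
            if not (0.8 < v < 1.2):
                raise InvalidInputError(f"factor {v} outside (0.8, 1.2)")


@dataclass(frozen=True)
class PlanRecord:
    """One patient plan's pencil-beam factor triple."""

    patient: str
    field: int
    site: str
    csf: float
    psf: float
    cpsf: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise InvalidInputError(f"unknown site {self.site!r}")
        for v in (self.csf, self.psf, self.cpsf):
            if not (0.8 < v < 1.2):
                raise InvalidInputError(f"factor {v} outside (0.8, 1.2)")
        if abs(self.cpsf - round(self.csf * self.psf, 3)) > 0.001 + 1e-12:
            raise InvalidInputError(
                f"cpsf {self.cpsf} inconsistent with csf*psf for {self.patient}"
            )


def _fixture_text(name: str) -> str:
    ref = resources.files("protoscatter").joinpath(f"data/{name}.csv")
    try:
        data = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"fixture {name} not installed") from exc
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"fixture {name} corrupted (sha256 {digest})")
    return data.decode()


def load_table_fixture(name: str):
    """Load a packaged table fixture; ``table1`` gives 12
    :class:`FieldRecord`, ``table2`` gives 26 :class:`PlanRecord`."""
    if name not in _CHECKSUMS:
        raise InvalidInputError(f"unknown fixture {name!r}; use table1 or table2")
    from io import StringIO

    df = pd.read_csv(StringIO(_fixture_text(name)))
    if name == "table1":
        return [
            FieldRecord(r.site, int(r.field_id), r.tps_csf, r.mc_csf, r.tps_psf, r.mc_psf)
            for r in df.itertuples()
        ]
    return [
        PlanRecord(str(r.patient), int(r.field), r.site, r.csf, r.psf, r.cpsf)
        for r in df.itertuples()
    ]


def mean_abs_pp_difference(a, b) -> float:
    """Mean absolute difference between two factor lists, in percentage
    points (|a_i - b_i| * 100). Unrounded; round to one decimal for
    reporting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidInputError("need two equal-length non-empty factor lists")
    return float(np.mean(np.abs(a - b)) * 100.0)


def max_abs_pp_difference(a, b) -> float:
    """Largest absolute difference between two factor lists, in pp."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidInputError("need two equal-length non-empty factor lists")
    return float(np.max(np.abs(a - b)) * 100.0)


def mean_rel_pct_difference(a, b) -> float:
    """Mean relative difference |a-b|/b * 100; the alternative convention,
    emitted alongside the percentage-point one for transparency."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidInputError("need two equal-length non-empty factor lists")
    return float(np.mean(np.abs(a - b) / np.abs(b)) * 100.0)


_COLUMN_ALIASES = {
    # requesting the generic name on a mixed record list resolves to the
    # pencil-beam (TPS) value for FieldRecord and the plain one for PlanRecord
    "psf": ("tps_psf", "psf"),
    "csf": ("tps_csf", "csf"),
    "cpsf": (None, "cpsf"),
    "tps_psf": ("tps_psf", None),
    "tps_csf": ("tps_csf", None),
    "mc_psf": ("mc_psf", None),
    "mc_csf": ("mc_csf", None),
}


def column_values(records, column: str) -> np.ndarray:
    """Extract one factor column from FieldRecord/PlanRecord lists."""
    if column not in _COLUMN_ALIASES:
        raise InvalidInputError(f"unknown column {column!r}")
    f_attr, p_attr = _COLUMN_ALIASES[column]
    out = []
    for r in records:
        attr = f_attr if isinstance(r, FieldRecord) else p_attr
        if attr is None:
            raise InvalidInputError(
                f"column {column!r} not defined for {type(r).__name__}"
            )
        out.append(getattr(r, attr))
    return np.asarray(out, float)


def factor_range(records, column: str) -> tuple[float, float]:
    """(min, max) of a factor column over a record list."""
    vals = column_values(records, column)
    if vals.size == 0:
        raise InvalidInputError("empty record list")
    return float(vals.min()), float(vals.max())


def recompute_cpsf(record: PlanRecord) -> float:
    """CPSF = round(csf * psf, 3), the table's product column."""
    return round(record.csf * record.psf, 3)


def site_mean_differences(records, column: str = "psf") -> dict:
    """Per-site mean MC-vs-TPS absolute differences (pp) for field records;
    ``column`` is 'psf' or 'csf'."""
    if column not in ("psf", "csf"):
        raise InvalidInputError("column must be 'psf' or 'csf'")
    out = {}
    for site in SITES:
        rs = [r for r in records if r.site == site]
        if not rs:
            continue
        tps = column_values(rs, f"tps_{column}")
        mc = column_values(rs, f"mc_{column}")
        out[site] = mean_abs_pp_difference(tps, mc)
    return out


def results_summary() -> dict:
    """All agreement statistics recomputed from the packaged fixtures."""
    t1 = load_table_fixture("table1")
    t2 = load_table_fixture("table2")
    tps_psf = column_values(t1, "tps_psf")
    mc_psf = column_values(t1, "mc_psf")
    tps_csf = column_values(t1, "tps_csf")
    mc_csf = column_values(t1, "mc_csf")
    psf_site = site_mean_differences(t1, "psf")
    csf_site = site_mean_differences(t1, "csf")
    psf_all = factor_range(list(t1) + list(t2), "psf")
    csf_all = factor_range(list(t1) + list(t2), "csf")
    return {
        "n_fields_table1": len(t1),
        "n_plans_table2": len(t2),
        "psf_range": psf_all,
        "csf_range": csf_all,
        "psf_site_mean_diff_pp": psf_site,
        "csf_site_mean_diff_pp": csf_site,
        "psf_max_diff_pp": max_abs_pp_difference(tps_psf, mc_psf),
        "csf_max_diff_pp": max_abs_pp_difference(tps_csf, mc_csf),
        "csf_mean_diff_pp": mean_abs_pp_difference(tps_csf, mc_csf),
        "psf_mean_diff_rel_pct": mean_rel_pct_difference(tps_psf, mc_psf),
        "csf_mean_diff_rel_pct": mean_rel_pct_difference(tps_csf, mc_csf),
        "cpsf_recomputed": {
            f"{r.patient}{r.field}": recompute_cpsf(r) for r in t2
        },
    }
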