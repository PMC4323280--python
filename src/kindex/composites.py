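"""Z-based global criterion composites for the concurrent-validity analysis.

Each validation-battery total is standardized against the analysis cohort
((x - mean) / SD over complete cases, sample SD with n-1 by default) and the
z-scores are summed into three unit-weighted global criteria:

* global stress            = z(PSS-14 total) + z(ESI total)
* global psychopathology   = z(SCL-90-R somatization) + z(HSCL-25 total)
                             + z(PDS symptom severity)
* global trauma load       = z(PDS event count) + z(CFV total)

A composite is missing for a respondent exactly when any of its components
is missing (complete-case propagation), so composite Ns track component
completeness.  Because standardization uses the cohort itself, composites
are cohort-relative quantities, not externally normed scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ZeroSpreadError",
    "ZTransformParams",
    "z_transform",
    "global_stress",
    "global_psychopathology",
    "global_trauma_load",
    "build_composites",
    "COMPOSITE_COMPONENTS",
]

COMPOSITE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "global_stress": ("pss14_total", "esi_total"),
    "global_psychopathology": ("scl_somatization", "hscl_total", "pds_severity"),
    "global_trauma_load": ("pds_events", "cfv_total"),
}


class ZeroSpreadError(ValueError):
    """A variable to be standardized has no spread."""


@dataclass(frozen=True)
class ZTransformParams:
    variable: str
    mean: float
    sd: float
    n_complete: int


def z_transform(
    values, *, ddof: int = 1, name: str = "variable"
) -> tuple[pd.Series, ZTransformParams]:
    """Standardize to mean 0 / SD 1 over complete cases; missing propagates.

    Parameters
    ----------
    values
        Sequence or Series of real values with NaN/None marking missing.
    ddof
        Degrees-of-freedom correction for the SD: 1 (sample SD, default)
        or 0 (population SD).
    name
        Variable name used in error messages and the returned parameters.

    Raises
    ------
    ZeroSpreadError
        If the complete cases are constant.
    ValueError
        If fewer than 2 complete values are available.
    """
    s = pd.Series(values, dtype="float64")
    complete = s.dropna()
    if len(complete) < 2:
        raise ValueError(
            f"z-transform of {name!r} needs >= 2 complete values, "
            f"got {len(complete)}"
        )
    mean = float(complete.mean())
    sd = float(complete.std(ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise ZeroSpreadError(f"{name!r} has zero spread; cannot standardize")
    z = (s - mean) / sd
    return z, ZTransformParams(name, mean, sd, len(complete))


def _z_sum(
    components: Mapping[str, "pd.Series"], *, ddof: int = 1
) -> tuple[pd.Series, dict[str, ZTransformParams]]:
    zs: dict[str, pd.Series] = {}
    params: dict[str, ZTransformParams] = {}
    for name, vals in components.items():
        zs[name], params[name] = z_transform(vals, ddof=ddof, name=name)
    frame = pd.DataFrame(zs)
    # complete-case: the sum is missing when any component z is missing
    total = frame.sum(axis=1, min_count=frame.shape[1])
    return total, params


def global_stress(pss14_total, esi_total, *, ddof: int = 1):
    """z(PSS-14) + z(ESI) per respondent; returns (composite, z-params)."""
    return _z_sum(
        {"pss14_total": pd.Series(pss14_total, dtype="float64"),
         "esi_total": pd.Series(esi_total, dtype="float64")},
        ddof=ddof,
    )


def global_psychopathology(scl_somatization, hscl_total, pds_severity, *, ddof: int = 1):
    """z(SCL somatization) + z(HSCL-25 total) + z(PDS severity)."""
    return _z_sum(
        {"scl_somatization": pd.Series(scl_somatization, dtype="float64"),
         "hscl_total": pd.Series(hscl_total, dtype="float64"),
         "pds_severity": pd.Series(pds_severity, dtype="float64")},
        ddof=ddof,
    )


def global_trauma_load(pds_events, cfv_total, *, ddof: int = 1):
    """z(PDS event count) + z(CFV total)."""
    return _z_sum(
        {"pds_events": pd.Series(pds_events, dtype="float64"),
         "cfv_total": pd.Series(cfv_total, dtype="float64")},
        ddof=ddof,
    )


def build_composites(totals: pd.DataFrame, *, ddof: int = 1) -> tuple[pd.DataFrame, dict]:
    """Build all three global composites from a cohort totals table.

    ``totals`` needs the columns named in :data:`COMPOSITE_COMPONENTS`
    (``hscl_total`` may be absent if ``hscl_anxiety``/``hscl_depression``
    are present, in which case it is formed as their sum first).

    Returns the composite frame (indexed like ``totals``) and a dict of
    per-composite standardization parameters (cohort mean/SD per component).
    """
    df = totals.copy()
    if "hscl_total" not in df.columns:
        if {"hscl_anxiety", "hscl_depression"} <= set(df.columns):
            df["hscl_total"] = df["hscl_anxiety"] + df["hscl_depression"]
        else:
            raise KeyError(
                "totals must provide 'hscl_total' or both "
                "'hscl_anxiety' and 'hscl_depression'"
            )
    out = pd.DataFrame(index=df.index)
    all_params: dict[str, dict[str, ZTransformParams]] = {}
    for comp, cols in COMPOSITE_COMPONENTS.items():
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise KeyError(f"totals lacks columns {missing_cols} for {comp}")
        out[comp], all_params[comp] = _z_sum(
            {c: df[c].astype("float64") for c in cols}, ddof=ddof
        )
    return out, all_params
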