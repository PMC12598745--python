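"""15N-urea quantification from GC–MS selected-ion-monitoring peak areas.

Derivatized urea elutes as a single GC peak whose molecular ions at
m/z 153, 154 and 155 correspond to 14,14N-urea, 14,15N-urea and
15,15N-urea respectively. The raw 15N fraction of an injection is the
area fraction

    f_raw = S155 / (S153 + S155)

which a linear calibration (slope ``a``, intercept ``b``, fit on
standards of known 15N%) maps to the calibrated percentage

    15N% = f_raw × a + b .

With a known amount of unlabelled (14N) urea spiked into each sample as
an internal calibrant, the 15N-urea concentration follows from the
measured 15N/14N ratio times the calibrant concentration, and the
ambient (pre-spike) 14N-urea concentration follows symmetrically from
the 14N% and the 15N-urea concentration of the same sample.

An optional three-ion mode also counts the mixed 14,15N ion
(``f = (S155 + S154/2) / (S153 + S154 + S155)``); the two-ion formula
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BelowDetectionError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidValueError,
)

__all__ = [
    "GcmsInjection",
    "CalibrationStandard",
    "CalibrationCurve",
    "InternalStandard",
    "raw_15n_fraction",
    "fit_calibration",
    "calibrated_15n_percent",
    "conc_15n_urea",
    "conc_14n_urea_ambient",
    "quantify_injections",
]


@dataclass(frozen=True)
class GcmsInjection:
    """SIM peak areas of one injection. s168/s170 are confirmatory ions,
    parsed and stored but not used in quantification."""

    injection_id: str
    s153: float
    s155: float
    s154: float = 0.0
    s168: float = 0.0
    s170: float = 0.0
    role: str = "sample"  # standard, sample, control

    def __post_init__(self) -> None:
        for a in (self.s153, self.s154, self.s155, self.s168, self.s170):
            if a < 0:
                raise InvalidValueError("peak areas must be non-negative")


@dataclass(frozen=True)
class CalibrationStandard:
    known_15n_fraction: float  # in [0, 1]
    injection: GcmsInjection

    def __post_init__(self) -> None:
        if not (0.0 <= self.known_15n_fraction <= 1.0):
            raise InvalidValueError("known 15N fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CalibrationCurve:
    a: float  # slope, maps raw area fraction -> 15N percent
    b: float  # intercept
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidValueError("calibration needs at least 3 points")


#: identity response: raw fraction maps straight to percent
IDENTITY_CURVE = CalibrationCurve(a=100.0, b=0.0, r_squared=1.0, n_points=3)


@dataclass(frozen=True)
class InternalStandard:
    """Unlabelled urea spiked into each liquid sample before derivatization."""

    amount_umol: float = 0.05
    sample_volume_ml: float = 0.200

    def __post_init__(self) -> None:
        if self.amount_umol <= 0 or self.sample_volume_ml <= 0:
            raise InvalidValueError("internal-standard amount and volume must be positive")

    @property
    def concentration_mM(self) -> float:
        return self.amount_umol / self.sample_volume_ml  # μmol/ml ≡ mmol/l


def raw_15n_fraction(inj: GcmsInjection, use_three_ion: bool = False,
                     area_floor: float = 0.0) -> float:
    """Uncalibrated 15N area fraction of an injection."""
    total = inj.s153 + inj.s155 + (inj.s154 if use_three_ion else 0.0)
    if total <= 0 or total < area_floor:
        raise BelowDetectionError(
            f"injection {inj.injection_id}: total quantifier area {total} below "
            f"detection floor"
        )
    if use_three_ion:
        return (inj.s155 + inj.s154 / 2.0) / total
    return inj.s155 / total


def fit_calibration(standards: list[CalibrationStandard],
                    use_three_ion: bool = False) -> CalibrationCurve:
    """Least-squares line mapping raw area fraction to known 15N% (0–100)."""
    if len({round(s.known_15n_fraction, 12) for s in standards}) < 3:
        raise InsufficientDataError(
            "calibration needs standards at >=3 distinct 15N fractions"
        )
    raw = np.array([raw_15n_fraction(s.injection, use_three_ion) for s in standards])
    known_pct = np.array([s.known_15n_fraction * 100.0 for s in standards])
    if np.ptp(raw) == 0.0:
        raise DegenerateDesignError("all standards yield identical raw fractions")
    fit = stats.linregress(raw, known_pct)
    return CalibrationCurve(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, len(standards))


def calibrated_15n_percent(inj: GcmsInjection, curve: CalibrationCurve,
                           use_three_ion: bool = False) -> tuple[float, bool]:
    """Calibrated 15N% of an injection, clamped to [0, 100].

    Returns ``(percent, clamped)`` where ``clamped`` flags that the raw
    line evaluated outside the physical range.
    """
    pct = raw_15n_fraction(inj, use_three_ion) * curve.a + curve.b
    clamped = pct < 0.0 or pct > 100.0
    return float(np.clip(pct, 0.0, 100.0)), clamped


def conc_15n_urea(inj: GcmsInjection, curve: CalibrationCurve,
                  istd: InternalStandard | None = None,
                  use_three_ion: bool = False) -> float:
    """15N-urea concentration (mmol/l) via the internal calibrant.

    The measured 15N/14N urea ratio ``f/(1−f)`` times the calibrant
    concentration gives the labelled-urea concentration; all 14N signal
    is attributed to the spiked calibrant.
    """
    istd = istd or InternalStandard()
    pct, _ = calibrated_15n_percent(inj, curve, use_three_ion)
    f = pct / 100.0
    if f >= 1.0:
        raise InvalidValueError(
            f"injection {inj.injection_id}: no 14N internal-standard signal "
            "(calibrated fraction is 1); concentration undefined"
        )
    return f / (1.0 - f) * istd.concentration_mM


def conc_14n_urea_ambient(f14_percent: float, c15_mM: float) -> float:
    """Ambient 14N-urea concentration from the 14N% and the 15N-urea
    concentration of the same sample: ``c15 × f14 / (100 − f14)``."""
    if not (0.0 <= f14_percent < 100.0):
        raise InvalidValueError("14N percent must lie in [0, 100)")
    if c15_mM < 0:
        raise InvalidValueError("15N-urea concentration must be non-negative")
    return c15_mM * f14_percent / (100.0 - f14_percent)


def quantify_injections(table: pd.DataFrame,
                        istd: InternalStandard | None = None,
                        use_three_ion: bool = False,
                        area_floor: float = 0.0) -> pd.DataFrame:
    """Table-level workflow: fit the calibration on ``role == 'standard'``
    rows (column ``known_15n_fraction``) and quantify every sample row.

    Expects columns injection_id, role, s153, s155 and optionally s154,
    s168, s170, known_15n_fraction plus pass-through metadata columns
    (time_h, replicate, ...). Injections below the detection floor are
    reported with missing quantities rather than zero.
    """
    istd = istd or InternalStandard()

    def _inj(row: pd.Series) -> GcmsInjection:
        return GcmsInjection(
            injection_id=str(row["injection_id"]),
            s153=float(row["s153"]),
            s155=float(row["s155"]),
            s154=float(row.get("s154", 0.0) or 0.0),
            s168=float(row.get("s168", 0.0) or 0.0),
            s170=float(row.get("s170", 0.0) or 0.0),
            role=str(row.get("role", "sample")),
        )

    standards = [
        CalibrationStandard(float(row["known_15n_fraction"]), _inj(row))
        for _, row in table[table["role"] == "standard"].iterrows()
    ]
    curve = fit_calibration(standards, use_three_ion)

    rows = []
    for _, row in table.iterrows():
        rec = {c: row[c] for c in table.columns}
        try:
            inj = _inj(row)
            raw = raw_15n_fraction(inj, use_three_ion, area_floor)
            pct, clamped = calibrated_15n_percent(inj, curve, use_three_ion)
            c15 = conc_15n_urea(inj, curve, istd, use_three_ion)
            rec.update(raw_fraction=raw, n15_percent=pct,
                       conc_15N_mM=c15, clamped=clamped)
        except (BelowDetectionError, InvalidValueError):
            rec.update(raw_fraction=np.nan, n15_percent=np.nan,
                       conc_15N_mM=np.nan, clamped=False)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["calibration"] = curve
    return out
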