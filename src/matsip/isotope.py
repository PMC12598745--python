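"""Isotope-notation conversions against the international reference standards.

All heavy/light isotope bookkeeping in the package funnels through this
module: δ notation (‰ versus the international standard), heavy/light
isotope ratios (dimensionless) and heavy-atom fractions (dimensionless,
in [0, 1)) are three representations of the same measurement, and the
reference ratios below are the single source of truth for converting
between them.

The standards are the Vienna Peedee Belemnite carbon ratio and the
atmospheric dinitrogen nitrogen ratio:

    13C/12C (VPDB)  = 0.0111802
    15N/14N (air)   = 0.0036765

δ notation is defined as ``(R_sample / R_standard - 1) * 1000`` in ‰,
and the atom fraction of the heavy isotope is ``x = R / (1 + R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidValueError

__all__ = [
    "REFERENCE_STANDARDS",
    "ReferenceStandards",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_atom_fraction",
    "atom_fraction_to_ratio",
    "natural_atom_fraction",
    "convert_n2_rate",
]


@dataclass(frozen=True)
class ReferenceStandards:
    """The two international isotope reference ratios anchoring δ conversions."""

    r_vpdb_c: float = 0.0111802  # 13C/12C, Vienna Peedee Belemnite
    r_air_n: float = 0.0036765  # 15N/14N, atmospheric N2

    def __post_init__(self) -> None:
        for r in (self.r_vpdb_c, self.r_air_n):
            if not (0.0 < r < 1.0):
                raise InvalidValueError(f"reference ratio {r} outside (0, 1)")

    def ratio(self, element: str) -> float:
        """Reference heavy/light ratio for element ``'C'`` or ``'N'``."""
        if element == "C":
            return self.r_vpdb_c
        if element == "N":
            return self.r_air_n
        raise InvalidValueError(f"unknown element {element!r}; expected 'C' or 'N'")


REFERENCE_STANDARDS = ReferenceStandards()


def delta_to_ratio(delta, element: str):
    """Convert δ (‰) to a heavy/light isotope ratio.

    Parameters
    ----------
    delta : float or array-like
        δ value(s) in ‰ relative to the element's standard. Must be ≥ −1000
        (−1000 ‰ is complete depletion of the heavy isotope).
    element : {'C', 'N'}

    Returns
    -------
    float or ndarray
        ``R_std * (delta / 1000 + 1)``.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000.0):
        raise InvalidValueError("delta below -1000 permil is unphysical")
    out = REFERENCE_STANDARDS.ratio(element) * (delta / 1000.0 + 1.0)
    return out if out.ndim else float(out)


def ratio_to_delta(ratio, element: str):
    """Convert a heavy/light isotope ratio to δ (‰). Exact inverse of
    :func:`delta_to_ratio`."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0.0):
        raise InvalidValueError("isotope ratio must be non-negative")
    out = (ratio / REFERENCE_STANDARDS.ratio(element) - 1.0) * 1000.0
    return out if out.ndim else float(out)


def ratio_to_atom_fraction(ratio):
    """Heavy-atom fraction ``x = R / (1 + R)`` from a heavy/light ratio."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0.0):
        raise InvalidValueError("isotope ratio must be non-negative")
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def atom_fraction_to_ratio(x):
    """Heavy/light ratio ``R = x / (1 - x)`` from a heavy-atom fraction."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x >= 1.0)):
        raise InvalidValueError("atom fraction must lie in [0, 1)")
    out = x / (1.0 - x)
    return out if out.ndim else float(out)


def natural_atom_fraction(element: str) -> float:
    """Natural-abundance heavy-atom fraction, derived from the standard ratio
    (≈0.0110566 for carbon, ≈0.0036630 for nitrogen)."""
    return ratio_to_atom_fraction(REFERENCE_STANDARDS.ratio(element))


def convert_n2_rate(rate_nmol_n2_per_g_per_day):
    """Convert a dinitrogen fixation rate from nmol N2/g dry/day to
    μmol N/g dry/h.

    Each N2 carries two N atoms, a day has 24 h, and 1000 nmol = 1 μmol,
    so the factor is ``2 / 24 / 1000``.
    """
    rate = np.asarray(rate_nmol_n2_per_g_per_day, dtype=float)
    if np.any(rate < 0.0):
        raise InvalidValueError("rate must be non-negative")
    out = rate * 2.0 / 24.0 / 1000.0
    return out if out.ndim else float(out)
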