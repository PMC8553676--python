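"""Unit conversions between check size, spatial frequency and acuity.

Conventions
-----------
A checkerboard's dominant spatial frequency is taken along the check edge,
one cycle spanning two checks::

    SF [cpd] = 60 / (2 * check size [arcmin])

The diagonal-fundamental convention (an extra factor of sqrt(2)) is available
via ``diagonal=True``; the acuity conversion factor absorbs the choice, so
the default is the simpler edge convention.

Decimal acuity and logMAR are reciprocal measures::

    logMAR = -log10(decimal acuity)

Decimal acuity is related to the spatial-frequency limit by a multiplicative
conversion factor (decimal acuity per cpd) whose default here is a placeholder
calibration constant: it makes a limit of 17.6 cpd correspond to decimal
acuity 1.0 (logMAR 0.0). Clinical deployments must calibrate this factor
against behavioural acuity; it is an explicit argument everywhere downstream.
"""

from __future__ import annotations

import math

#: Decimal acuity per cycle/degree. Placeholder calibration constant.
DEFAULT_CONVERSION_FACTOR: float = 1.0 / 17.6

#: Ceiling applied to decimal acuity estimates (logMAR >= -0.2).
ACUITY_CLIP_CEILING: float = 1.6


def sf_from_check_size(check_size_arcmin: float, *, diagonal: bool = False) -> float:
    """Dominant spatial frequency (cycles/degree) of a checkerboard.

    Parameters
    ----------
    check_size_arcmin
        Check edge length in arc minutes.
    diagonal
        Use the diagonal-fundamental convention (multiplies by sqrt(2)).
    """
    if check_size_arcmin <= 0:
        raise ValueError(f"check size must be positive, got {check_size_arcmin}")
    sf = 60.0 / (2.0 * check_size_arcmin)
    if diagonal:
        sf *= math.sqrt(2.0)
    return sf


def logmar_from_decimal(decimal_acuity: float) -> float:
    """logMAR = -log10(decimal acuity)."""
    if decimal_acuity <= 0:
        raise ValueError(f"decimal acuity must be positive, got {decimal_acuity}")
    return -math.log10(decimal_acuity)


def decimal_from_logmar(logmar: float) -> float:
    """Decimal acuity = 10**(-logMAR)."""
    return 10.0 ** (-logmar)


def sf_limit_from_logmar(
    logmar: float, conversion_factor: float = DEFAULT_CONVERSION_FACTOR
) -> float:
    """Spatial-frequency limit (cpd) corresponding to a logMAR acuity.

    Inverse of the decimal = factor * sf_limit conversion; used by the
    synthetic generator to plant ground-truth tuning curves.
    """
    if conversion_factor <= 0:
        raise ValueError("conversion factor must be positive")
    return decimal_from_logmar(logmar) / conversion_factor
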