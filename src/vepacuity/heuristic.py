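"""Tuning-curve construction and heuristic acuity extrapolation.

The tuning curve relates noise-corrected first-harmonic amplitude to the
log spatial frequency of the stimulus. The heuristic estimator selects
points on the descending flank based on response significance, fits a
straight line in (log10 SF, amplitude) space, and takes the abscissa
intercept as the spatial-frequency limit of the visual system. A
conversion factor maps that limit to decimal acuity, which is clipped to
<= 1.6 (logMAR >= -0.2) before the logMAR transform, because estimates far
beyond the stimulus range are imprecise and clinically irrelevant.

Point selection, spurious-significance handling and the trailing-point
rule are all explicit configuration points: published descriptions of
this family of algorithms leave room for variation, and the defaults here
are the package's own reconstruction (see docs/methods.md).

Numerical note: before the least-squares fit, amplitudes are normalized
by their maximum and reduced to single precision. The fit therefore
depends only on amplitude *ratios*, making the documented invariance —
scaling every amplitude by a common factor leaves the estimate unchanged
— hold exactly rather than only to rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conversion import ACUITY_CLIP_CEILING, DEFAULT_CONVERSION_FACTOR
from .spectral import SpectralResponse


@dataclass
class TuningCurve:
    """Ordered tuning curve plus significance overrides.

    ``points`` are sorted by increasing ``log_sf`` (one per check size).
    ``overrides`` are indices forced non-significant; an overridden point
    is treated as non-significant by all downstream logic regardless of
    its measured p-value (the manual correction for spurious
    significances arising from multiple testing across check sizes).
    """

    points: list[SpectralResponse]
    overrides: set[int] = field(default_factory=set)

    def is_significant(self, index: int) -> bool:
        """Effective significance of a point (override-aware)."""
        return self.points[index].significant and index not in self.overrides

    @property
    def significance_pattern(self) -> list[bool]:
        return [self.is_significant(i) for i in range(len(self.points))]

    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude_corrected for p in self.points])

    def log_sfs(self) -> np.ndarray:
        return np.array([p.log_sf for p in self.points])


@dataclass(frozen=True)
class AcuityEstimate:
    """Outcome of an acuity estimation.

    When ``status == "ok"``: ``sf_limit`` (cpd), ``decimal_acuity``,
    ``logmar`` (= -log10(decimal)), the ``clipped`` flag, the fitted
    ``slope`` (uV per log10 cpd, on the normalized scale) and the curve
    indices used in the fit. When ``status == "no_estimate"`` every
    numeric field is ``None`` and ``reason`` says why.
    """

    status: str
    sf_limit: float | None = None
    decimal_acuity: float | None = None
    logmar: float | None = None
    clipped: bool = False
    slope: float | None = None
    fit_points: tuple[int, ...] = ()
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("ok", "no_estimate"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "no_estimate":
            if any(v is not None for v in (self.sf_limit, self.decimal_acuity, self.logmar)):
                raise ValueError("no_estimate outcomes carry no numeric fields")
        else:
            if self.sf_limit is None or self.sf_limit <= 0:
                raise ValueError("ok outcomes require a positive sf_limit")
            if (self.decimal_acuity is None) != (self.logmar is None):
                raise ValueError("decimal_acuity and logmar must be set together")
            if self.decimal_acuity is not None and not math.isclose(
                self.logmar, -math.log10(self.decimal_acuity), abs_tol=1e-12
            ):
                raise ValueError("logmar must equal -log10(decimal_acuity)")


def build_curve(responses: list[SpectralResponse | None]) -> TuningCurve:
    """Assemble a tuning curve from per-check-size spectral responses.

    ``None`` entries (recordings with no usable segments) are dropped.
    Requires at least two points with distinct spatial frequencies;
    duplicates are rejected naming the offending check size.
    """
    points = [r for r in responses if r is not None]
    if len(points) < 2:
        raise ValueError("need at least 2 spectral responses to build a tuning curve")
    points = sorted(points, key=lambda r: r.log_sf)
    for a, b in zip(points, points[1:]):
        if a.spatial_frequency == b.spatial_frequency:
            raise ValueError(
                f"duplicate spatial frequency {a.spatial_frequency:g} cpd "
                f"(check size {a.check_size:g} arcmin)"
            )
    return TuningCurve(points=points)


def flag_spurious(
    curve: TuningCurve,
    mode: str | list[int] = "auto",
) -> TuningCurve:
    """Mark spurious significances as non-significant.

    With a list of indices (``mode=[...]``, the manual route) exactly
    those points are overridden. With ``mode="auto"`` a convenience rule
    emulates the manual correction: a significant point is overridden iff
    it is separated from the low-SF contiguous block of significant
    points by at least two consecutive non-significant points — isolated
    high-SF significances beyond a clearly extinguished response are the
    typical multiple-testing artifact.

    Returns a new curve; the input is not modified.
    """
    n = len(curve.points)
    if isinstance(mode, (list, tuple, set)):
        indices = set(int(i) for i in mode)
        bad = [i for i in indices if i < 0 or i >= n]
        if bad:
            raise IndexError(f"override indices out of range: {sorted(bad)} (curve has {n} points)")
        return TuningCurve(points=list(curve.points), overrides=set(curve.overrides) | indices)
    if mode != "auto":
        raise ValueError("mode must be 'auto' or a list of indices")

    sig = curve.significance_pattern
    overrides = set(curve.overrides)
    try:
        first_sig = sig.index(True)
    except ValueError:
        return TuningCurve(points=list(curve.points), overrides=overrides)
    i = first_sig
    while i < n and sig[i]:
        i += 1
    # walk beyond the low-SF block; once a gap of >= 2 consecutive
    # non-significant points has occurred, everything after is spurious
    gap = 0
    cut = False
    for j in range(i, n):
        if not sig[j]:
            gap += 1
            continue
        if cut or gap >= 2:
            cut = True
            overrides.add(j)
        else:
            gap = 0
    return TuningCurve(points=list(curve.points), overrides=overrides)


def fit_sf_limit(
    curve: TuningCurve,
    *,
    include_trailing_nonsig: bool = False,
) -> AcuityEstimate:
    """Fit the descending flank and extrapolate to the SF limit.

    Steps: (1) the peak is the significant point with maximal
    noise-corrected amplitude (ties broken toward lower SF, keeping more
    of the descending flank in the fit); (2) the fit set is every point
    from the peak through the highest-SF significant point, at measured
    amplitude — optionally plus the first non-significant point beyond it
    (``include_trailing_nonsig``); (3) least squares of normalized
    amplitude against log10 SF; (4) ``sf_limit = 10**x0`` where x0 is the
    abscissa intercept.

    Returns a ``no_estimate`` outcome when no point is significant, fewer
    than two fit points exist, the fitted slope is non-negative, or all
    fit amplitudes are zero. Only the SF-limit fields are populated; use
    :func:`to_acuity` or :func:`estimate_acuity` for the acuity fields.
    """
    sig = curve.significance_pattern
    sig_idx = [i for i, s in enumerate(sig) if s]
    if not sig_idx:
        return AcuityEstimate(status="no_estimate", reason="no significant response at any check size")
    amps = curve.amplitudes()
    peak = max(sig_idx, key=lambda i: (amps[i], -i))
    last_sig = sig_idx[-1]
    fit_idx = list(range(peak, last_sig + 1))
    if include_trailing_nonsig and last_sig + 1 < len(curve.points):
        fit_idx.append(last_sig + 1)
    if len(fit_idx) < 2:
        return AcuityEstimate(
            status="no_estimate",
            reason="fewer than 2 points on the descending flank",
            fit_points=tuple(fit_idx),
        )
    x = curve.log_sfs()[fit_idx]
    y = amps[fit_idx]
    ymax = y.max()
    if ymax <= 0:
        return AcuityEstimate(
            status="no_estimate",
            reason="all fit amplitudes are zero",
            fit_points=tuple(fit_idx),
        )
    # scale-free fit: normalized ratios, reduced to single precision so a
    # common amplitude factor cancels exactly (see module docstring)
    r = (y / ymax).astype(np.float32).astype(float)
    slope, intercept = np.polyfit(x, r, 1)
    if slope >= 0:
        return AcuityEstimate(
            status="no_estimate",
            reason=f"non-negative fitted slope ({slope:.3g})",
            fit_points=tuple(fit_idx),
        )
    x0 = -intercept / slope
    return AcuityEstimate(
        status="ok",
        sf_limit=float(10.0**x0),
        slope=float(slope),
        fit_points=tuple(fit_idx),
    )


def to_acuity(
    sf_limit: float,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    *,
    clip_ceiling: float = ACUITY_CLIP_CEILING,
) -> tuple[float, float, bool]:
    """Convert an SF limit (cpd) to (decimal acuity, logMAR, clipped).

    ``decimal = conversion_factor * sf_limit`` clipped to
    ``<= clip_ceiling`` (default 1.6, i.e. logMAR >= -0.2), then
    ``logmar = -log10(decimal)``. Clipping happens on the decimal scale,
    before the logMAR transform.
    """
    if sf_limit <= 0:
        raise ValueError(f"sf_limit must be positive, got {sf_limit}")
    if conversion_factor <= 0:
        raise ValueError(f"conversion_factor must be positive, got {conversion_factor}")
    decimal = conversion_factor * sf_limit
    clipped = decimal > clip_ceiling
    if clipped:
        decimal = clip_ceiling
    return decimal, -math.log10(decimal), clipped


def estimate_acuity(
    curve: TuningCurve,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    *,
    include_trailing_nonsig: bool = False,
    clip_ceiling: float = ACUITY_CLIP_CEILING,
) -> AcuityEstimate:
    """Full heuristic: fit the SF limit, then convert to acuity."""
    fit = fit_sf_limit(curve, include_trailing_nonsig=include_trailing_nonsig)
    if fit.status != "ok":
        return fit
    decimal, logmar, clipped = to_acuity(
        fit.sf_limit, conversion_factor, clip_ceiling=clip_ceiling
    )
    return AcuityEstimate(
        status="ok",
        sf_limit=fit.sf_limit,
        decimal_acuity=decimal,
        logmar=logmar,
        clipped=clipped,
        slope=fit.slope,
        fit_points=fit.fit_points,
    )
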