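"""Spectral read-outs of the misfolding assay.

The primary feature is the 1656.0/1623.5 absorbance ratio of a subject's
processed difference spectrum: the α-helical/random-coil lobe over the
β-sheet lobe.  Low ratios indicate β-sheet-enriched (misfolded) αSyn.
Secondary read-outs are the absolute Amide-I peak position, the
center-of-mass maximum (intensity-weighted mean wavenumber over the top
80–90 % of the band — a position estimator that stays robust at small
signal), the lobe integrals of a group difference spectrum, and the plateau
amplitude of a binding-kinetics trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .qc import QCReport
from .spectra_io import KineticsTrace, Spectrum

__all__ = ["FeatureSet", "BandIntegrals", "InvalidFeatureError",
           "absolute_max", "com_max", "spectral_ratio", "band_integrals",
           "kinetic_amplitude", "RATIO_NUMERATOR_NU", "RATIO_DENOMINATOR_NU"]

AMIDE1_WINDOW = (1600.0, 1700.0)
RATIO_NUMERATOR_NU = 1656.0
RATIO_DENOMINATOR_NU = 1623.5


class InvalidFeatureError(ValueError):
    """A feature could not be computed (e.g. nonpositive ratio denominator);
    the subject must be flagged, never silently dropped."""


@dataclass
class FeatureSet:
    """Per-subject spectral read-outs."""

    abs_max: float                      # cm⁻¹
    com_max: float                      # cm⁻¹
    ratio_1656_1623: float              # dimensionless
    kinetic_amplitude: Optional[float] = None  # AU
    qc: Optional[QCReport] = None
    valid: bool = True


def absolute_max(s: Spectrum, window: tuple = AMIDE1_WINDOW) -> float:
    """Wavenumber of the maximum absorbance in ``window``.

    Ties are broken toward the higher wavenumber (grids are stored
    descending, so the first maximum wins).
    """
    nu, a = s.window(*window)
    return float(nu[int(np.argmax(a))])


def com_max(s: Spectrum, window: tuple = AMIDE1_WINDOW, fraction: float = 0.85) -> float:
    """Center-of-mass maximum over the top ``fraction`` of the band.

    Let A* be the window maximum; over grid points with A ≥ fraction·A*, the
    read-out is Σ ν·A / Σ A.  The default 0.85 is the midpoint of the
    recommended 0.80–0.90 range; both endpoints are legal.
    """
    if not 0.80 <= fraction <= 0.90:
        raise ValueError("fraction must be in [0.80, 0.90]")
    nu, a = s.window(*window)
    peak = float(a.max())
    if peak <= 0:
        raise InvalidFeatureError("nonpositive band maximum in Amide-I window")
    mask = a >= fraction * peak
    return float((nu[mask] * a[mask]).sum() / a[mask].sum())


def spectral_ratio(s: Spectrum, nu_num: float = RATIO_NUMERATOR_NU,
                   nu_den: float = RATIO_DENOMINATOR_NU) -> float:
    """A(nu_num)/A(nu_den) with linear interpolation at the query points.

    Computed on the processed (smoothed) per-subject difference spectrum.
    Raises :class:`InvalidFeatureError` on a nonpositive denominator so the
    caller can flag the subject.
    """
    num = s.interp(nu_num)
    den = s.interp(nu_den)
    if den <= 0:
        raise InvalidFeatureError(
            f"nonpositive absorbance {den:.3g} at {nu_den} cm⁻¹")
    return float(num / den)


@dataclass
class BandIntegrals:
    """Lobe integrals of a group difference spectrum (AU·cm⁻¹, magnitudes)."""

    positive_integral: float   # β-sheet lobe (near 1623.5 cm⁻¹)
    negative_integral: float   # helix/random-coil lobe magnitude (near 1656 cm⁻¹)
    pos_window: tuple
    neg_window: tuple


def band_integrals(diff: Spectrum, pos_window: tuple = (1608.0, 1640.0),
                   neg_window: tuple = (1640.0, 1672.0)) -> BandIntegrals:
    """Trapezoidal integrals of the two difference-spectrum lobes.

    Default windows are ±16 cm⁻¹ around the printed lobe positions with the
    boundary at 1640 cm⁻¹; each lobe is integrated with its sign and
    reported as a magnitude.  Windows may share at most one point.
    """
    lo = max(pos_window[0], neg_window[0])
    hi = min(pos_window[1], neg_window[1])
    if hi > lo:
        raise ValueError("integration windows overlap by more than one point")
    out = {}
    for key, (wlo, whi) in (("pos", pos_window), ("neg", neg_window)):
        nu, a = diff.window(wlo, whi)
        # ascending order for a positively-oriented integral
        out[key] = abs(float(np.trapezoid(a[::-1], nu[::-1])))
    return BandIntegrals(positive_integral=out["pos"], negative_integral=out["neg"],
                         pos_window=pos_window, neg_window=neg_window)


def kinetic_amplitude(k: KineticsTrace) -> float:
    """Plateau amplitude: mean of the final 10 % of the trace minus the mean
    of the first 5 % (offset-invariant)."""
    n = len(k)
    if n < 10:
        raise ValueError("kinetics trace too short (need >= 10 points)")
    head = max(1, int(round(0.05 * n)))
    tail = max(1, int(round(0.10 * n)))
    return float(k.absorbance[-tail:].mean() - k.absorbance[:head].mean())
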