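"""Spectral processing chain for immuno-infrared difference spectroscopy.

Canonical stage order: average → water-vapor correction → baseline
correction → difference (wash − background) → smoothing → (normalisation).
Each stage appends a record to the processing trace stored in
``Spectrum.meta["trace"]``, including fitted scalars (vapor coefficient,
baseline anchors, normalisation factor), so a processed spectrum is fully
auditable.

Algorithms the upstream acquisition software leaves unspecified are chosen
here as follows and recorded in every trace:

* Water vapor: the correction coefficient α of ``s − α·ref`` is fitted by
  least squares on *second differences* over the 1900–1700 cm⁻¹ diagnostic
  window.  Second differencing suppresses broad protein/baseline features
  and isolates the sharp rotational vapor lines, and the 1800–1900 cm⁻¹
  part of the window is protein-free.
* Baseline: a straight line through the mean absorbance of two anchor
  windows (1800–1750 and 1490–1480 cm⁻¹ by default), flanking the amide
  region.
* Smoothing: Savitzky–Golay, default window 9 points, polynomial order 3.
  Signal-to-noise is always evaluated on unsmoothed spectra; smoothing sets
  ``meta["smoothed"]`` so the QC stage can enforce that.
* Normalisation: unit Amide-I maximum (window 1700–1600 cm⁻¹).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import Spectrum

__all__ = [
    "average_spectra",
    "difference_spectrum",
    "correct_water_vapor",
    "correct_baseline",
    "smooth",
    "normalize_amide1",
    "group_difference",
    "DEFAULT_BASELINE_ANCHORS",
    "VAPOR_DIAGNOSTIC_WINDOW",
    "AMIDE1_WINDOW",
]

AMIDE1_WINDOW = (1600.0, 1700.0)
VAPOR_DIAGNOSTIC_WINDOW = (1700.0, 1900.0)
DEFAULT_BASELINE_ANCHORS = ((1750.0, 1800.0), (1480.0, 1490.0))


def _traced(s: Spectrum, a: np.ndarray, stage: str, **params) -> Spectrum:
    out = s.with_absorbance(a)
    trace = list(out.meta.get("trace", ()))
    trace.append({"stage": stage, **params})
    out.meta["trace"] = trace
    return out


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a common grid."""
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    ref = spectra[0]
    for i, s in enumerate(spectra):
        if not ref.same_grid(s):
            raise ValueError(f"grid mismatch: spectrum {i} differs from spectrum 0")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return _traced(ref, mean, "average", n_averaged=len(spectra))


def difference_spectrum(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Sample-wash minus sample-background: the bound-protein spectrum."""
    if not sample.same_grid(background):
        raise ValueError("sample and background are on different grids")
    return _traced(sample, sample.absorbance - background.absorbance, "difference")


def correct_water_vapor(s: Spectrum, vapor_ref: Spectrum,
                        window: tuple = VAPOR_DIAGNOSTIC_WINDOW) -> Spectrum:
    """Subtract α·vapor_ref, α minimising Σ(Δ²(s − α·ref))² over ``window``.

    The optimum is the one-parameter least-squares solution
    α = ⟨Δ²ref, Δ²s⟩ / ⟨Δ²ref, Δ²ref⟩ on the second differences of the
    diagnostic window.
    """
    if not s.same_grid(vapor_ref):
        raise ValueError("spectrum and vapor reference are on different grids")
    mask = s.window_mask(*window)
    if mask.sum() < 3:
        raise ValueError("vapor diagnostic window too small on this grid")
    d2s = np.diff(s.absorbance[mask], n=2)
    d2v = np.diff(vapor_ref.absorbance[mask], n=2)
    denom = float(d2v @ d2v)
    if denom <= 0:
        raise ValueError("degenerate vapor reference (no structure in window)")
    alpha = float(d2v @ d2s) / denom
    corrected = s.absorbance - alpha * vapor_ref.absorbance
    return _traced(s, corrected, "water_vapor", alpha=alpha, window=window)


def correct_baseline(s: Spectrum,
                     anchors: tuple = DEFAULT_BASELINE_ANCHORS,
                     method: str = "linear") -> Spectrum:
    """Baseline correction.

    ``method="linear"`` (default) subtracts the straight line through the
    mean absorbance of the two anchor windows.  ``method="rubber_band"``
    subtracts the lower convex hull of the spectrum (anchors ignored) — a
    conservative alternative for curved baselines.
    """
    if method == "rubber_band":
        x, y = s.ascending
        hull = [0]
        for i in range(1, x.size):  # lower-hull sweep (monotone chain)
            while len(hull) >= 2:
                (i0, i1) = hull[-2], hull[-1]
                cross = ((x[i1] - x[i0]) * (y[i] - y[i0])
                         - (y[i1] - y[i0]) * (x[i] - x[i0]))
                if cross <= 0:
                    hull.pop()
                else:
                    break
            hull.append(i)
        base_asc = np.interp(x, x[hull], y[hull])
        corrected = s.absorbance - base_asc[::-1]
        return _traced(s, corrected, "baseline", method=method,
                       n_hull_points=len(hull))
    if method != "linear":
        raise ValueError(f"unknown baseline method {method!r}")
    if len(anchors) != 2:
        raise ValueError("exactly two anchor windows are required")
    xs, ys = [], []
    for lo, hi in anchors:
        mask = s.window_mask(lo, hi)
        if not mask.any():
            raise ValueError(f"baseline anchor window [{lo}, {hi}] empty on grid")
        xs.append(float(s.wavenumbers[mask].mean()))
        ys.append(float(s.absorbance[mask].mean()))
    slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    line = ys[0] + slope * (s.wavenumbers - xs[0])
    return _traced(s, s.absorbance - line, "baseline", method=method,
                   anchors=anchors, anchor_means=tuple(ys))


def smooth(s: Spectrum, window_points: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky–Golay smoothing; marks the output ``smoothed`` in meta."""
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= polyorder:
        raise ValueError("window_points must exceed polyorder")
    if window_points > len(s):
        raise ValueError("smoothing window exceeds grid length")
    a = savgol_filter(s.absorbance, window_points, polyorder)
    out = _traced(s, a, "smooth", window_points=window_points, polyorder=polyorder)
    out.meta["smoothed"] = True
    return out


def normalize_amide1(s: Spectrum, window: tuple = AMIDE1_WINDOW) -> Spectrum:
    """Scale so the Amide-I window maximum equals one."""
    _, vals = s.window(*window)
    peak = float(vals.max())
    if peak <= 0:
        raise ValueError("nonpositive Amide-I maximum: failed run, cannot normalize")
    return _traced(s, s.absorbance / peak, "normalize_amide1", scale=1.0 / peak)


def group_difference(positives: Sequence[Spectrum], controls: Sequence[Spectrum],
                     anchors: tuple = DEFAULT_BASELINE_ANCHORS) -> Spectrum:
    """Normalized misfolding-group mean minus normalized control-group mean.

    Each spectrum is max-normalized in the Amide-I window before averaging;
    the resulting difference is baseline-corrected.  A positive lobe near
    1623.5 cm⁻¹ reflects enriched β-sheet structure in the positive group,
    the negative lobe near 1656.0 cm⁻¹ the matching loss of α-helical/
    random-coil structure.
    """
    if not positives or not controls:
        raise ValueError("both groups must be nonempty")
    pos_mean = average_spectra([normalize_amide1(s) for s in positives])
    ctl_mean = average_spectra([normalize_amide1(s) for s in controls])
    diff = difference_spectrum(pos_mean, ctl_mean)
    out = correct_baseline(diff, anchors)
    out.meta["n_positive"] = len(positives)
    out.meta["n_control"] = len(controls)
    return out
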