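"""Spectrum acceptance gates.

Two gates decide whether a subject's difference spectrum enters the
analysis:

* Amide-I/Amide-II peak ratio in the closed interval [1.10, 1.50].
  Values outside indicate distorted spectra (water-background changes or
  temperature instability during acquisition).
* Signal-to-noise ≥ 20, with S the mean absorbance between 1560 and
  1540 cm⁻¹ and N the root-mean-square of the absorbance between 1800 and
  1900 cm⁻¹, always computed on the *unsmoothed* spectrum.

Both statistics are invariant under a global gain, so the gates act on
spectral shape and noise floor, not protein amount alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Spectrum

__all__ = ["QCReport", "amide_ratio", "signal_to_noise", "run_qc",
           "AMIDE1_WINDOW", "AMIDE2_WINDOW", "SIGNAL_WINDOW", "NOISE_WINDOW",
           "AMIDE_RATIO_BOUNDS", "SNR_MINIMUM"]

AMIDE1_WINDOW = (1600.0, 1700.0)
AMIDE2_WINDOW = (1500.0, 1580.0)
SIGNAL_WINDOW = (1540.0, 1560.0)
NOISE_WINDOW = (1800.0, 1900.0)
AMIDE_RATIO_BOUNDS = (1.10, 1.50)
SNR_MINIMUM = 20.0


@dataclass
class QCReport:
    """Outcome of both acceptance gates for one subject's spectrum."""

    amide_ratio: float
    snr: float
    passed: bool
    reasons: list = field(default_factory=list)
    windows: dict = field(default_factory=dict)


def amide_ratio(s: Spectrum) -> float:
    """Amide-I window maximum over Amide-II window maximum.

    Computed on the unnormalized difference spectrum; a nonpositive Amide-II
    maximum means no protein signal and is an error.
    """
    _, a1 = s.window(*AMIDE1_WINDOW)
    _, a2 = s.window(*AMIDE2_WINDOW)
    a2max = float(a2.max())
    if a2max <= 0:
        raise ValueError("nonpositive Amide-II maximum: no protein signal")
    return float(a1.max()) / a2max


def signal_to_noise(s_unsmoothed: Spectrum, mean_subtract: bool = False) -> float:
    """S/N with S = mean(1540–1560 cm⁻¹) and N = RMS(1800–1900 cm⁻¹).

    The RMS is taken of the absorbance values themselves (no mean
    subtraction) by default; ``mean_subtract=True`` selects the
    standard-deviation variant.  Refuses smoothed input: smoothing deflates
    N and would inflate the gate.
    """
    if s_unsmoothed.meta.get("smoothed", False):
        raise ValueError("signal_to_noise requires an unsmoothed spectrum")
    _, sig = s_unsmoothed.window(*SIGNAL_WINDOW)
    _, noi = s_unsmoothed.window(*NOISE_WINDOW)
    if mean_subtract:
        noi = noi - noi.mean()
    n = float(np.sqrt(np.mean(noi * noi)))
    s_val = float(sig.mean())
    if n == 0.0:
        warnings.warn("zero noise in 1800-1900 window; S/N reported as inf")
        return np.inf
    return s_val / n


def run_qc(s: Spectrum, s_unsmoothed: Spectrum) -> QCReport:
    """Apply both gates; ``s`` is the processed (possibly smoothed) difference
    spectrum, ``s_unsmoothed`` its unsmoothed counterpart for the S/N gate.

    Boundary semantics: ratio 1.10 and 1.50 are included; S/N exactly 20
    passes (only S/N < 20 is excluded).
    """
    reasons = []
    try:
        ratio = amide_ratio(s)
    except ValueError:
        ratio = np.nan
        reasons.append("amide_ratio")
    else:
        if not (AMIDE_RATIO_BOUNDS[0] <= ratio <= AMIDE_RATIO_BOUNDS[1]):
            reasons.append("amide_ratio")
    snr = signal_to_noise(s_unsmoothed)
    if snr < SNR_MINIMUM:
        reasons.append("snr")
    return QCReport(
        amide_ratio=float(ratio), snr=float(snr), passed=not reasons,
        reasons=reasons,
        windows={"amide1": AMIDE1_WINDOW, "amide2": AMIDE2_WINDOW,
                 "signal": SIGNAL_WINDOW, "noise": NOISE_WINDOW},
    )
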