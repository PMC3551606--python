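"""Tryptophan-fluorescence emission maxima and the pH 4->6 blue shift (MEWD).

A molten-globule state exposes tryptophan side chains to solvent
(red-shifted emission); on folding at higher pH the indole rings become
buried and the emission maximum moves to shorter wavelengths.  The maximum
emission wavelength deviation, MEWD = lambda_max(pH 4) - lambda_max(pH 6),
is therefore positive for constructs that undergo the disorder-to-order
transition and near zero for those that do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EmissionSpectrum", "SpectrumPeak", "MewdResult", "find_peak", "mewd"]


@dataclass
class EmissionSpectrum:
    """A fluorescence emission trace for one construct at one pH."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    variant: str = ""
    ph: float = float("nan")

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.wavelength_nm) < 20:
            raise ValueError("emission spectrum needs at least 20 points")
        if len(self.wavelength_nm) != len(self.intensity):
            raise ValueError("wavelength and intensity lengths differ")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.wavelength_nm.min() < 250 or self.wavelength_nm.max() > 450:
            raise ValueError("wavelengths outside [250, 450] nm")


@dataclass(frozen=True)
class SpectrumPeak:
    lambda_max: float
    F_max: float
    boundary: bool = False  # argmax fell on the first/last grid point


@dataclass(frozen=True)
class MewdResult:
    mewd: float
    peak_pH4: SpectrumPeak
    peak_pH6: SpectrumPeak
    variant: str = ""


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 3:
        raise ValueError("smoothing window must be an odd integer >= 3")
    kernel = np.ones(window) / window
    return np.convolve(np.pad(y, window // 2, mode="edge"), kernel, mode="valid")


def find_peak(
    spec: EmissionSpectrum,
    refine: bool = True,
    round_to: float | None = 0.5,
    smooth_window: int | None = None,
) -> SpectrumPeak:
    """Locate the emission maximum of a spectrum.

    The grid argmax is refined by a three-point parabola through the argmax
    and its neighbours, then rounded to the nearest ``round_to`` nm (default
    0.5 nm, the resolution at which emission maxima are conventionally
    reported).  ``refine=False`` returns the plain grid argmax.  When the
    argmax sits on a grid boundary the peak is returned un-refined with a
    warning and ``boundary=True``.
    """
    lam = spec.wavelength_nm
    y = spec.intensity if smooth_window is None else _moving_average(spec.intensity, smooth_window)
    if np.ptp(y) == 0:
        raise ValueError("spectrum has constant intensity: no peak")
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        warnings.warn(
            f"emission maximum at spectrum boundary ({lam[i]:.1f} nm); returned un-refined",
            stacklevel=2,
        )
        return SpectrumPeak(lambda_max=float(lam[i]), F_max=float(y[i]), boundary=True)
    lam_peak, f_peak = float(lam[i]), float(y[i])
    if refine:
        ym1, y0, yp1 = y[i - 1], y[i], y[i + 1]
        denom = ym1 - 2.0 * y0 + yp1
        if denom < 0:  # genuine local maximum; flat tops fall back to the grid point
            delta = 0.5 * (ym1 - yp1) / denom
            step = 0.5 * (lam[i + 1] - lam[i - 1])
            lam_peak = float(lam[i] + delta * step)
            f_peak = float(y0 - 0.25 * (ym1 - yp1) * delta)
    if round_to:
        lam_peak = round(lam_peak / round_to) * round_to
    return SpectrumPeak(lambda_max=lam_peak, F_max=f_peak)


def mewd(
    spec_pH4: EmissionSpectrum,
    spec_pH6: EmissionSpectrum,
    force: bool = False,
    **peak_kwargs,
) -> MewdResult:
    """Blue shift between the pH 4 and pH 6 spectra of one construct.

    MEWD = lambda_max(pH 4) - lambda_max(pH 6); positive values indicate a
    blue shift, i.e. tryptophan burial on folding.  The two spectra must
    come from the same construct unless ``force``.
    """
    if spec_pH4.variant != spec_pH6.variant and not force:
        raise ValueError(
            f"variant mismatch: {spec_pH4.variant!r} vs {spec_pH6.variant!r}; pass force=True"
        )
    p4 = find_peak(spec_pH4, **peak_kwargs)
    p6 = find_peak(spec_pH6, **peak_kwargs)
    return MewdResult(
        mewd=p4.lambda_max - p6.lambda_max,
        peak_pH4=p4,
        peak_pH6=p6,
        variant=spec_pH4.variant,
    )
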