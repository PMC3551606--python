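"""Two-state thermal-unfolding analysis of circular-dichroism melts.

The model is the standard two-state expression with linear folded and
unfolded baselines and a van't Hoff free energy (constant-enthalpy
approximation, dCp = 0):

    y(T) = [(Yn + Mn*T) + (Yd + Md*T) * K(T)] / (1 + K(T))
    K(T) = exp(-dG(T) / (R*T)),   dG(T) = dH * (1 - T/Tm)

with T in Kelvin, dH the van't Hoff unfolding enthalpy (kcal/mol) and Tm
the midpoint of the transition.  The fit is parameterised by (dH, Tm) for
numerical stability; the unfolding entropy is derived as dS = dH/Tm.

From a converged fit one obtains the unfolding free energy dG_u(T), the
fraction of unfolded molecules, and ddG_u between a mutant and a reference
construct at a common reference temperature (negative = destabilising).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "R_KCAL",
    "CELSIUS_OFFSET",
    "MeltCurve",
    "TwoStateFit",
    "ThermoSummary",
    "mdeg_to_mre",
    "two_state_model",
    "two_state_signal",
    "fit_two_state",
    "gibbs_free_energy",
    "fraction_unfolded",
    "delta_delta_G",
]

log = logging.getLogger(__name__)

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987204e-3
CELSIUS_OFFSET = 273.15

#: cooperativity rule: minimum van't Hoff enthalpy (kcal/mol) and minimum
#: transition amplitude in units of the residual RMSE
MIN_COOPERATIVE_DH = 5.0
MIN_AMPLITUDE_RMSE_RATIO = 3.0


@dataclass
class MeltCurve:
    """A temperature-indexed CD trace for one construct at one pH."""

    temperature_c: np.ndarray
    signal: np.ndarray
    signal_unit: str = "mdeg"  # "mdeg" or "mre"
    wavelength_nm: float = 208.0
    variant: str = ""
    ph: float = float("nan")

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_unit not in {"mdeg", "mre"}:
            raise ValueError(f"signal_unit must be 'mdeg' or 'mre', got {self.signal_unit!r}")
        if len(self.temperature_c) < 10:
            raise ValueError("melt curve needs at least 10 points")
        if len(self.temperature_c) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")
        if not np.all(np.diff(self.temperature_c) > 0):
            raise ValueError("temperatures must be strictly ascending")
        if self.temperature_c.min() < -10 or self.temperature_c.max() > 120:
            raise ValueError("temperatures outside [-10, 120] degC")

    @property
    def temperature_k(self) -> np.ndarray:
        return self.temperature_c + CELSIUS_OFFSET


@dataclass
class TwoStateFit:
    """Fitted baselines and van't Hoff thermodynamics of one melt.

    Yn/Mn (Yd/Md) are intercept and slope of the pre- (post-) transition
    baseline in signal units (per K); dH in kcal/mol; Tm in K.  dS is
    derived as dH/Tm.  ``cooperative`` is a qualitative label: curves with a
    vanishing enthalpy or a transition amplitude buried in the residual
    noise are called "non-cooperative".
    """

    Yn: float
    Mn: float
    Yd: float
    Md: float
    dH: float
    Tm: float
    rmse: float = float("nan")
    converged: bool = True
    cooperative: str = "cooperative"
    stderr: dict = field(default_factory=dict)
    variant: str = ""
    ph: float = float("nan")

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")

    @property
    def dS(self) -> float:
        """Unfolding entropy, kcal mol^-1 K^-1 (= dH/Tm)."""
        return self.dH / self.Tm

    @property
    def tm_c(self) -> float:
        return self.Tm - CELSIUS_OFFSET

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "pH": self.ph,
            "Yn_signal": self.Yn,
            "Mn_signal_per_K": self.Mn,
            "Yd_signal": self.Yd,
            "Md_signal_per_K": self.Md,
            "dH_kcal_per_mol": self.dH,
            "dS_kcal_per_mol_K": self.dS,
            "Tm_K": self.Tm,
            "Tm_C": self.tm_c,
            "rmse_signal": self.rmse,
            "converged": self.converged,
            "cooperative": self.cooperative,
            "stderr": self.stderr,
        }


@dataclass
class ThermoSummary:
    """dG_u, fraction unfolded, and optional ddG_u at a reference temperature."""

    dG: float
    T_ref: float
    f_unfolded: float
    ddG_u: float | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_unfolded <= 1.0:
            raise ValueError("fraction unfolded must lie in [0, 1]")


def mdeg_to_mre(
    signal: np.ndarray | float,
    concentration: float,
    n_residues: int,
    path_length: float,
) -> np.ndarray | float:
    """Convert a CD signal in millidegrees to mean residue ellipticity.

    [theta] = signal / (10 * path_length_cm * concentration_M * n_residues),
    in deg cm^2 dmol^-1.  Linear (homogeneous of degree 1) in the signal.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive (mol/L)")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if path_length <= 0:
        raise ValueError("path_length must be positive (cm)")
    out = np.asarray(signal, dtype=float) / (10.0 * path_length * concentration * n_residues)
    return out if np.ndim(signal) else float(out)


def two_state_model(T, Yn, Mn, Yd, Md, dH, Tm):
    """Two-state melt signal at temperature T (K) for explicit parameters."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive Kelvin")
    dG = dH * (1.0 - T / Tm)
    # clip the exponent so extreme trial parameters cannot overflow
    expo = np.clip(-dG / (R_KCAL * T), -500.0, 500.0)
    K = np.exp(expo)
    return ((Yn + Mn * T) + (Yd + Md * T) * K) / (1.0 + K)


def two_state_signal(params: TwoStateFit, T) -> np.ndarray:
    """Predicted CD signal of a fitted two-state model at temperature T (K)."""
    return two_state_model(T, params.Yn, params.Mn, params.Yd, params.Md, params.dH, params.Tm)


def _initial_guesses(T: np.ndarray, y: np.ndarray) -> dict:
    n = len(T)
    k = max(2, int(round(0.15 * n)))
    mn, yn = np.polyfit(T[:k], y[:k], 1)
    md, yd = np.polyfit(T[-k:], y[-k:], 1)
    dy = np.gradient(y, T)
    tm0 = float(T[np.argmax(np.abs(dy))])
    tm0 = float(np.clip(tm0, T.min() + 1.0, T.max() - 1.0))
    return {"Yn": yn, "Mn": mn, "Yd": yd, "Md": md, "Tm": tm0}


def _transition_amplitude(fit: TwoStateFit) -> float:
    return abs((fit.Yd + fit.Md * fit.Tm) - (fit.Yn + fit.Mn * fit.Tm))


def fit_two_state(curve: MeltCurve) -> TwoStateFit:
    """Least-squares fit of the two-state model to a melt curve.

    Initialisation: Tm from the temperature of maximum |dY/dT| (central
    differences), baselines by ordinary least squares on the first and last
    15% of points, with three optimizer restarts at dH0 in {15, 30, 60}
    kcal/mol; the restart with the lowest residual RMSE wins.  ``converged``
    is True only when the optimizer met tolerance and the fitted Tm lies
    inside the scanned temperature range.
    """
    T = curve.temperature_k
    y = curve.signal
    if T.max() - T.min() < 30.0:
        raise ValueError("melt must span at least 30 degC for a stable fit")

    guesses = _initial_guesses(T, y)
    model = lmfit.Model(two_state_model, independent_vars=["T"])

    best = None
    for dh0 in (15.0, 30.0, 60.0):
        params = model.make_params(
            Yn=guesses["Yn"], Mn=guesses["Mn"], Yd=guesses["Yd"], Md=guesses["Md"],
            dH=dh0, Tm=guesses["Tm"],
        )
        params["Tm"].set(min=150.0, max=500.0)
        params["dH"].set(min=1e-3, max=500.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(y, params, T=T)
        except Exception:  # pragma: no cover - optimizer blow-ups are rare
            continue
        rmse = float(np.sqrt(np.mean(result.residual**2)))
        if best is None or rmse < best[0]:
            best = (rmse, result)

    if best is None:  # pragma: no cover
        raise RuntimeError("all optimizer restarts failed")
    rmse, result = best
    p = result.params
    tm = float(p["Tm"].value)
    in_range = T.min() <= tm <= T.max()
    converged = bool(result.success) and in_range
    stderr = {
        name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
        for name in ("Yn", "Mn", "Yd", "Md", "dH", "Tm")
    }
    fit = TwoStateFit(
        Yn=float(p["Yn"].value), Mn=float(p["Mn"].value),
        Yd=float(p["Yd"].value), Md=float(p["Md"].value),
        dH=float(p["dH"].value), Tm=tm,
        rmse=rmse, converged=converged, stderr=stderr,
        variant=curve.variant, ph=curve.ph,
    )
    amp = _transition_amplitude(fit)
    span = float(np.ptp(y)) + 1.0
    noncoop = (
        not converged
        or fit.dH < MIN_COOPERATIVE_DH
        or amp < MIN_AMPLITUDE_RMSE_RATIO * rmse
        or amp < 1e-8 * span  # degenerate: no resolvable transition at all
    )
    fit.cooperative = "non-cooperative" if noncoop else "cooperative"
    if not converged:
        log.warning("two-state fit did not converge for %s (Tm=%.1f K)", curve.variant, tm)
    return fit


def gibbs_free_energy(fit: TwoStateFit, T_ref: float) -> float:
    """Unfolding free energy dG_u = dH*(1 - T_ref/Tm), kcal/mol, at T_ref (K)."""
    if T_ref <= 0:
        raise ValueError("reference temperature must be positive Kelvin")
    return fit.dH * (1.0 - T_ref / fit.Tm)


def fraction_unfolded(fit: TwoStateFit, T_ref: float) -> float:
    """Equilibrium fraction of unfolded molecules at T_ref (K): K/(1+K)."""
    dg = gibbs_free_energy(fit, T_ref)
    expo = np.clip(-dg / (R_KCAL * T_ref), -500.0, 500.0)
    K = float(np.exp(expo))
    return K / (1.0 + K)


def delta_delta_G(
    fit_ref: TwoStateFit, fit_mut: TwoStateFit, T_ref: float, force: bool = False
) -> float:
    """ddG_u = dG_u(mutant) - dG_u(reference) at T_ref; negative = destabilising."""
    if not force:
        for f in (fit_ref, fit_mut):
            if not f.converged:
                raise ValueError(
                    f"fit for {f.variant or 'construct'} did not converge; pass force=True to override"
                )
    return gibbs_free_energy(fit_mut, T_ref) - gibbs_free_energy(fit_ref, T_ref)


def summarize(
    fit: TwoStateFit, T_ref: float, reference: TwoStateFit | None = None
) -> ThermoSummary:
    """Bundle dG_u, fraction unfolded, and optional ddG_u versus a reference."""
    ddg = None
    ref_name = ""
    if reference is not None:
        ddg = delta_delta_G(reference, fit, T_ref)
        ref_name = reference.variant
    return ThermoSummary(
        dG=gibbs_free_energy(fit, T_ref),
        T_ref=T_ref,
        f_unfolded=fraction_unfolded(fit, T_ref),
        ddG_u=ddg,
        reference=ref_name,
    )
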