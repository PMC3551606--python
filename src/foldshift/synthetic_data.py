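"""Synthetic spectroscopy and sequence data with the structure the analysis assumes.

Each generator emulates one acquisition mode of the study design:

* CD melts on a 4-96 degC grid in 2 degC steps, a two-state transition with
  linear pre/post baselines plus i.i.d. Gaussian noise scaled to the
  transition amplitude;
* fluorescence emission spectra on a 290-400 nm grid (0.5 nm step) as a
  single Gaussian peak plus additive noise;
* linear AMC-release progress curves, singly or as control/inhibited pairs
  honouring a target residual fraction;
* random protein sequences, optionally with one exact motif match planted
  per sequence at a recorded position.

All randomness flows through an explicit integer seed; identical parameters
and seed give bit-identical outputs.
"""

from __future__ import annotations

import numpy as np

from foldshift.cd_thermo import CELSIUS_OFFSET, MeltCurve, two_state_model
from foldshift.fluor_shift import EmissionSpectrum
from foldshift.inhibition_assay import ProgressCurve
from foldshift.motif_scan import AA20, MotifPattern

__all__ = [
    "melt_grid_c",
    "emission_grid_nm",
    "gen_melt",
    "gen_emission",
    "gen_progress",
    "gen_progress_pair",
    "gen_sequences",
]

AA_ALPHABET = "".join(sorted(AA20))


def melt_grid_c(start: float = 4.0, stop: float = 96.0, step: float = 2.0) -> np.ndarray:
    """Default thermal-scan grid: 4 to 96 degC in 2 degC increments."""
    return np.arange(start, stop + 0.5 * step, step)


def emission_grid_nm(start: float = 290.0, stop: float = 400.0, step: float = 0.5) -> np.ndarray:
    """Default emission grid: 290 to 400 nm, 0.5 nm step."""
    return np.arange(start, stop + 0.5 * step, step)


def gen_melt(
    dH: float,
    Tm_c: float,
    Yn: float = -12.0,
    Mn: float = 0.01,
    Yd: float = -2.0,
    Md: float = -0.005,
    noise_frac: float = 0.0,
    seed: int = 0,
    grid_c: np.ndarray | None = None,
    variant: str = "",
    ph: float = 6.0,
) -> MeltCurve:
    """Simulate a two-state CD melt with linear baselines and Gaussian noise.

    ``noise_frac`` scales the noise standard deviation to the transition
    amplitude (the baseline separation at Tm), so noise levels transfer
    across signal units.  A Tm outside 0-120 degC is generated anyway with a
    warning, matching how a real instrument would happily record it.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if not 0.0 <= Tm_c <= 120.0:
        import warnings

        warnings.warn(f"Tm {Tm_c:.1f} degC outside the 0-120 degC sanity window", stacklevel=2)
    grid_c = melt_grid_c() if grid_c is None else np.asarray(grid_c, dtype=float)
    T = grid_c + CELSIUS_OFFSET
    tm_k = Tm_c + CELSIUS_OFFSET
    y = two_state_model(T, Yn, Mn, Yd, Md, dH, tm_k)
    amplitude = abs((Yd + Md * tm_k) - (Yn + Mn * tm_k))
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_frac * amplitude, size=y.shape)
    return MeltCurve(temperature_c=grid_c, signal=y, signal_unit="mdeg", variant=variant, ph=ph)


def gen_emission(
    lambda_max: float,
    F_max: float,
    width_nm: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_nm: np.ndarray | None = None,
    variant: str = "",
    ph: float = float("nan"),
) -> EmissionSpectrum:
    """Simulate a single-peak emission spectrum: Gaussian of given centre/width."""
    grid_nm = emission_grid_nm() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    if not grid_nm.min() <= lambda_max <= grid_nm.max():
        raise ValueError(
            f"lambda_max {lambda_max} nm outside the grid [{grid_nm.min()}, {grid_nm.max()}]"
        )
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    y = F_max * np.exp(-((grid_nm - lambda_max) ** 2) / (2.0 * width_nm**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return EmissionSpectrum(wavelength_nm=grid_nm, intensity=y, variant=variant, ph=ph)


def gen_progress(
    rate: float,
    duration_s: float = 300.0,
    n_points: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    inhibitor: str = "",
    concentration_uM: float = float("nan"),
) -> ProgressCurve:
    """Simulate a linear early-phase AMC-release progress curve."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.linspace(0.0, duration_s, n_points)
    y = rate * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return ProgressCurve(
        time_s=t, fluorescence=y, inhibitor=inhibitor, concentration_uM=concentration_uM
    )


def gen_progress_pair(
    control_rate: float,
    residual_fraction: float,
    duration_s: float = 300.0,
    n_points: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    inhibitor: str = "",
    concentration_uM: float = float("nan"),
) -> tuple[ProgressCurve, ProgressCurve]:
    """Paired control/inhibited curves whose true rate ratio is ``residual_fraction``."""
    if not 0.0 <= residual_fraction:
        raise ValueError("residual_fraction must be >= 0")
    control = gen_progress(control_rate, duration_s, n_points, noise_sd, seed)
    inhibited = gen_progress(
        control_rate * residual_fraction,
        duration_s,
        n_points,
        noise_sd,
        seed + 1,
        inhibitor=inhibitor,
        concentration_uM=concentration_uM,
    )
    return control, inhibited


def _realize_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for element in pattern.elements:
        if isinstance(element, int):
            out.append("".join(rng.choice(list(AA_ALPHABET), size=element)))
        else:
            out.append(str(rng.choice(sorted(element))))
    return "".join(out)


def gen_sequences(
    n: int,
    length: int,
    planted_motif: MotifPattern | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Random protein sequences, optionally each carrying one planted motif match.

    Residues are uniform over the 20 standard amino acids.  When a motif is
    given, one exact realisation is written into each sequence at a random
    position, recorded (1-based) in the returned dict.  Note the random
    background can produce additional chance matches.
    """
    rng = np.random.default_rng(seed)
    if planted_motif is not None and length < planted_motif.span:
        raise ValueError(
            f"length {length} shorter than motif span {planted_motif.span}"
        )
    records: list[tuple[str, str]] = []
    planted: dict[str, int] = {}
    for i in range(n):
        seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
        name = f"seq{i + 1}"
        if planted_motif is not None:
            site = _realize_motif(planted_motif, rng)
            start = int(rng.integers(0, length - planted_motif.span + 1))
            seq = seq[:start] + site + seq[start + len(site):]
            planted[name] = start + 1
        records.append((name, seq))
    return records, planted
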