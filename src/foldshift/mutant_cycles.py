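"""Double-mutant-cycle coupling energies between residue pairs.

A cycle consists of a background construct (wt), two single mutants (m1,
m2) and the double mutant (dm).  If the two mutated side chains do not
interact, the free-energy costs of the single mutations are additive; any
non-additivity is the pairwise interaction (coupling) energy

    ddG_int = (dG_wt - dG_m1) - (dG_m2 - dG_dm)
            = dG_wt - dG_m1 - dG_m2 + dG_dm

(the Horovitz-Fersht convention).  Positive ddG_int means the two side
chains favourably couple, e.g. through a salt bridge that contributes to
stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from foldshift.cd_thermo import TwoStateFit, gibbs_free_energy

__all__ = ["CycleSpec", "CycleResult", "coupling_energy", "run_cycle", "read_cycles"]


@dataclass(frozen=True)
class CycleSpec:
    """The four construct names of one double-mutant cycle."""

    cycle_id: str
    wt: str
    m1: str
    m2: str
    dm: str
    pair: str = ""

    def __post_init__(self) -> None:
        names = [self.wt, self.m1, self.m2, self.dm]
        if len(set(names)) != 4:
            raise ValueError(f"cycle {self.cycle_id}: the four construct names must be distinct")


@dataclass
class CycleResult:
    cycle_id: str
    ddG_int: float
    T_ref: float
    components: dict = field(default_factory=dict)
    stderr: float = float("nan")
    pair: str = ""

    def to_dict(self) -> dict:
        return {
            "cycle_id": self.cycle_id,
            "pair": self.pair,
            "ddG_int_kcal_per_mol": self.ddG_int,
            "T_ref_K": self.T_ref,
            **{f"dG_u_{k}": v for k, v in self.components.items()},
        }


def coupling_energy(g_wt: float, g_m1: float, g_m2: float, g_dm: float) -> float:
    """Coupling energy ddG_int = g_wt - g_m1 - g_m2 + g_dm (kcal/mol).

    Symmetric under exchange of the two single mutants; zero when the
    double mutant is exactly additive (g_dm = g_m1 + g_m2 - g_wt).
    """
    values = (g_wt, g_m1, g_m2, g_dm)
    if any(not math.isfinite(v) for v in values):
        raise ValueError(f"coupling_energy requires four finite dG_u values, got {values}")
    return g_wt - g_m1 - g_m2 + g_dm


def run_cycle(
    spec: CycleSpec,
    fits: Mapping[str, TwoStateFit],
    T_ref: float,
    force: bool = False,
) -> CycleResult:
    """Evaluate one double-mutant cycle from per-construct melt fits.

    Each construct's dG_u is computed at ``T_ref`` (K) from its fit, then
    combined by :func:`coupling_energy`.  Missing constructs raise an error
    naming them; non-converged fits raise unless ``force``.
    """
    components = {}
    stderr_sq = 0.0
    for role in ("wt", "m1", "m2", "dm"):
        name = getattr(spec, role)
        if name not in fits:
            raise KeyError(f"cycle {spec.cycle_id}: no fit for construct {name!r}")
        fit = fits[name]
        if not fit.converged and not force:
            raise ValueError(
                f"cycle {spec.cycle_id}: fit for {name!r} did not converge; pass force=True"
            )
        components[name] = gibbs_free_energy(fit, T_ref)
        # first-order propagation of the Tm/dH standard errors through
        # dG = dH (1 - T/Tm); summed in quadrature across the four legs
        se_dh = fit.stderr.get("dH", float("nan"))
        se_tm = fit.stderr.get("Tm", float("nan"))
        if math.isfinite(se_dh) and math.isfinite(se_tm):
            d_dh = 1.0 - T_ref / fit.Tm
            d_tm = fit.dH * T_ref / fit.Tm**2
            stderr_sq += (d_dh * se_dh) ** 2 + (d_tm * se_tm) ** 2
        else:
            stderr_sq = float("nan")
    ddg = coupling_energy(
        components[spec.wt], components[spec.m1], components[spec.m2], components[spec.dm]
    )
    return CycleResult(
        cycle_id=spec.cycle_id,
        ddG_int=ddg,
        T_ref=T_ref,
        components=components,
        stderr=math.sqrt(stderr_sq) if math.isfinite(stderr_sq) else float("nan"),
        pair=spec.pair,
    )


def read_cycles(path: str | Path) -> list[CycleSpec]:
    """Read a cycle manifest TSV with columns cycle_id, wt, m1, m2, dm[, pair]."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    required = {"cycle_id", "wt", "m1", "m2", "dm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cycle manifest missing columns {sorted(missing)}")
    return [
        CycleSpec(
            cycle_id=row["cycle_id"], wt=row["wt"], m1=row["m1"], m2=row["m2"],
            dm=row["dm"], pair=row.get("pair", ""),
        )
        for _, row in df.iterrows()
    ]
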