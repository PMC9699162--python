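"""SAPT0 component bookkeeping, unit conversions, two-point CBS
extrapolation and Boltzmann conformer populations.

The SAPT0 interaction energy is the sum of seven terms,

    E_int = E(1)_elst + E(1)_exch + E(2)_ind + E(2)_exch-ind
          + E(2)_disp + E(2)_exch-disp + δE_HF ,

where δE_HF is the residual completing the first four terms to the
supermolecular Hartree–Fock interaction energy.  *Effective* induction and
dispersion regroup the second-order terms with their exchange counterparts
(and δE_HF into induction), so that

    E_int = E_elst + E_exch + E_ind,eff + E_disp,eff        (exactly).

All energies are in millihartree (mH), the unit used throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "SaptComponents",
    "EffectiveComponents",
    "sapt0_total",
    "effective_components",
    "cbs_extrapolate",
    "cbs_rule_of_thumb",
    "convert_energy",
    "boltzmann_populations",
    "read_component_table",
    "KB_MH_PER_K",
    "HARTREE_KJ_PER_MOL",
]

#: Boltzmann constant in mH per kelvin (k_B * 298.15 K = 0.944 mH)
KB_MH_PER_K = 3.166811563e-6 * 1000.0
HARTREE_KJ_PER_MOL = 2625.4996
KCAL_KJ = 4.184

_UNIT_TO_HARTREE = {
    "hartree": 1.0,
    "mH": 1e-3,
    "kJ/mol": 1.0 / HARTREE_KJ_PER_MOL,
    "kcal/mol": KCAL_KJ / HARTREE_KJ_PER_MOL,
}


@dataclass
class SaptComponents:
    """The seven-term SAPT0 component vector (mH).

    ``delta_hf`` may be omitted when ``e_int_hf`` is supplied; it is then
    derived as e_int_hf − (elst + exch + ind + exch_ind) and never stored
    redundantly.
    """

    elst: float
    exch: float
    ind: float
    exch_ind: float
    disp: float
    exch_disp: float
    delta_hf: float | None = None
    e_int_hf: float | None = None

    def __post_init__(self) -> None:
        if self.exch < 0:
            import warnings

            warnings.warn(
                f"first-order exchange is negative ({self.exch} mH); "
                "physical SAPT inputs have E_exch >= 0",
                stacklevel=2,
            )

    def resolved_delta_hf(self) -> float:
        if self.delta_hf is not None:
            return self.delta_hf
        if self.e_int_hf is None:
            raise ValueError(
                "delta_hf cannot be resolved: supply delta_hf or e_int_hf"
            )
        return self.e_int_hf - (self.elst + self.exch + self.ind + self.exch_ind)


@dataclass
class EffectiveComponents:
    """Electrostatics, exchange and the effective induction/dispersion
    (mH); the four terms sum exactly to the SAPT0 total."""

    elst: float
    exch: float
    ind_eff: float
    disp_eff: float

    @property
    def total(self) -> float:
        return self.elst + self.exch + self.ind_eff + self.disp_eff


def sapt0_total(c: SaptComponents) -> float:
    """Sum of the seven SAPT0 terms; equivalently
    e_int_hf + disp + exch_disp when the HF interaction energy is given."""
    return (
        c.elst + c.exch + c.ind + c.exch_ind + c.disp + c.exch_disp
        + c.resolved_delta_hf()
    )


def effective_components(c: SaptComponents) -> EffectiveComponents:
    dhf = c.resolved_delta_hf()
    return EffectiveComponents(
        elst=c.elst,
        exch=c.exch,
        ind_eff=c.ind + c.exch_ind + dhf,
        disp_eff=c.disp + c.exch_disp,
    )


def cbs_extrapolate(e2: float, e3: float) -> tuple[float, float]:
    """Two-point inverse-cubic basis-set extrapolation.

    Fits E_L = E_inf + A/L**3 through the cardinal numbers L = 2, 3 and
    returns (E_inf, A).  Closed form: E_inf = e3 − (e2 − e3)·8/19,
    A = (e2 − e3)·216/19.
    """
    diff = e2 - e3
    return e3 - diff * 8.0 / 19.0, diff * 216.0 / 19.0


def cbs_rule_of_thumb(e_dz: float, factor: float = 4.0 / 3.0) -> float:
    """Crude CBS estimate by rescaling a double-zeta correlation
    interaction energy by ~4/3."""
    return e_dz * factor


def convert_energy(x: float, from_unit: str, to_unit: str) -> float:
    try:
        return x * _UNIT_TO_HARTREE[from_unit] / _UNIT_TO_HARTREE[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown energy unit {exc.args[0]!r}; known: {sorted(_UNIT_TO_HARTREE)}"
        ) from None


def boltzmann_populations(
    relative_energies: Sequence[float], temperature: float = 298.15
) -> list[float]:
    """Equilibrium fractions p_k ∝ exp(−E_k / k_B T) for energies in mH."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not all(math.isfinite(e) for e in relative_energies):
        raise ValueError("relative energies must be finite")
    emin = min(relative_energies)
    weights = [math.exp(-(e - emin) / (KB_MH_PER_K * temperature)) for e in relative_energies]
    z = sum(weights)
    return [w / z for w in weights]


# ---------------------------------------------------------------------------
# component-table reader
# ---------------------------------------------------------------------------

_ALIASES = {
    "elst": {"elst", "e_elst", "eelst", "eelst(10)", "e(1)elst", "electrostatics"},
    "exch": {"exch", "e_exch", "eexch", "eexch(10)", "e(1)exch", "exchange"},
    "ind": {"ind", "e_ind", "eind", "eind,resp(20)", "eind(20)", "e(2)ind",
            "induction"},
    "exch_ind": {"exch_ind", "exchind", "eexch-ind,resp(20)", "eexch-ind(20)",
                 "e(2)exch-ind", "exchange-induction"},
    "disp": {"disp", "e_disp", "edisp", "edisp(20)", "e(2)disp", "dispersion"},
    "exch_disp": {"exch_disp", "exchdisp", "eexch-disp(20)", "e(2)exch-disp",
                  "exchange-dispersion"},
    "e_int_hf": {"e_int_hf", "einthf", "e_hf", "hf"},
    "delta_hf": {"delta_hf", "dhf", "deltahf"},
}


def _canon(col: str) -> str | None:
    key = col.strip().lower().replace(" ", "")
    for canonical, names in _ALIASES.items():
        if key in names or key == canonical:
            return canonical
    return None


def read_component_table(path: str | Path) -> pd.DataFrame:
    """CSV/JSON reader for SAPT component tables (one complex per row).

    Component columns are recognised through header aliases; all other
    columns (labels, totals) pass through unchanged.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    rename = {c: _canon(c) for c in df.columns if _canon(c)}
    return df.rename(columns=rename)


def components_from_row(row) -> SaptComponents:
    """Build :class:`SaptComponents` from a table row (pandas Series or
    mapping) using canonical column names."""
    get = row.get if hasattr(row, "get") else row.__getitem__
    return SaptComponents(
        elst=float(get("elst")),
        exch=float(get("exch")),
        ind=float(get("ind")),
        exch_ind=float(get("exch_ind")),
        disp=float(get("disp")),
        exch_disp=float(get("exch_disp")),
        delta_hf=None if get("delta_hf") is None else float(get("delta_hf")),
        e_int_hf=None if get("e_int_hf") is None else float(get("e_int_hf")),
    )
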