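"""Sequence-specific intrinsic (chemical) amide exchange rates.

The unprotected-amide exchange rate ``k_ch`` of every backbone amide is the
sum of acid-, base- and water-catalyzed terms::

    k_ch = k_A * [H+] * F_acid  +  k_B * [OH-] * F_base  +  k_W * F_base

where ``k_A``, ``k_B``, ``k_W`` are the poly-DL-alanine reference rate
constants for the D-to-H exchange direction at 20 degC (Bai et al. 1993, the
parameter set behind the SPHERE calculator) and ``F_acid``/``F_base`` are the
products of the side-chain inductive factors of the residue carrying the
amide (lambda) and of its N-terminal neighbor (rho).  The water term shares
the base-catalysis factors.  Temperature is handled by Arrhenius corrections
of the three catalytic constants (Ea = 14 / 17 / 19 kcal/mol) together with
the temperature dependence of the water ion product.

Exchange is D-to-H in protonated solvent, so the read pH is used directly
(no pD glass-electrode correction).  Ionizable side chains (Asp, Glu, His)
titrate between their protonated and deprotonated factor sets.

The amide of residue 1 does not exist (free amine) and residue 2's amide
back-exchanges within the quench dead time, so both are excluded, as are
prolines (no amide H).  Terminal-group charge perturbations are not modeled;
positions next to the termini are never interpreted in TMD profiles.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide import PeptideSpec

# poly-DL-alanine reference rates, D->H exchange, 20 degC, log10 scale
# (k_A in 1/(M min), k_B in 1/(M min), k_W in 1/min)
LOG10_KA_REF = 1.40
LOG10_KB_REF = 10.00
LOG10_KW_REF = -1.60
T_REF = 293.15  # K

# Arrhenius activation energies, cal/mol
EA_ACID = 14_000.0
EA_BASE = 17_000.0
EA_WATER = 19_000.0
R_CAL = 1.987  # cal/(mol K)

# side-chain pKa values used for factor titration
SIDECHAIN_PKA = {"D": 3.87, "E": 4.33, "H": 7.00}

# water ion product pKw vs temperature (degC), CRC-style grid
_PKW_GRID_C = np.array([0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 60, 70, 80, 90, 100], float)
_PKW_GRID = np.array(
    [14.943, 14.734, 14.535, 14.346, 14.167, 13.997, 13.833, 13.680,
     13.535, 13.396, 13.262, 13.017, 12.800, 12.600, 12.420, 12.260]
)

BASE_DOMINANT_MIN_PH = 4.0


class TemperatureRangeError(ValueError):
    """Temperature outside the liquid-water validity range [273 K, 373 K]."""


def _load_factors() -> pd.DataFrame:
    with importlib.resources.files("dhxflex.data").joinpath("amide_factors.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col="res")


_FACTORS = _load_factors()


def pkw(temperature: float) -> float:
    """Interpolated pKw of H2O at ``temperature`` (kelvin)."""
    t_c = temperature - 273.15
    if not 273.0 <= temperature <= 373.0:
        raise TemperatureRangeError(
            f"temperature {temperature:.1f} K outside [273 K, 373 K]"
        )
    return float(np.interp(t_c, _PKW_GRID_C, _PKW_GRID))


def _arrhenius(ea_cal: float, temperature: float) -> float:
    return float(np.exp(-ea_cal / R_CAL * (1.0 / temperature - 1.0 / T_REF)))


def _titrated_factor(residue: str, column: str, h_conc: float, reduced_cys: bool) -> float:
    """Effective log10 inductive factor at the given [H+].

    For Asp/Glu/His the protonated and deprotonated factor sets are mixed on
    the linear scale, weighted by the Henderson-Hasselbalch species
    fractions; all other residues have a single factor set.
    """
    if residue == "C" and not reduced_cys:
        return float(_FACTORS.loc["C2", column])
    if residue in SIDECHAIN_PKA:
        ka = 10.0 ** (-SIDECHAIN_PKA[residue])
        f_prot = 10.0 ** _FACTORS.loc[residue + "0", column]
        f_deprot = 10.0 ** _FACTORS.loc[residue, column]
        mixed = (f_prot * h_conc + f_deprot * ka) / (h_conc + ka)
        return float(np.log10(mixed))
    return float(_FACTORS.loc[residue, column])


@dataclass
class IntrinsicRateTable:
    """Per-residue chemical exchange rates for one peptide.

    ``table`` has one row per exchange-competent residue (positions 1, 2 and
    prolines excluded) with columns ``position``, ``residue``, ``k_acid``,
    ``k_base``, ``k_water``, ``k_ch`` (all rates in 1/min).
    """

    peptide: PeptideSpec
    table: pd.DataFrame = field(repr=False)
    excluded: list[int] = field(default_factory=list)

    def positions(self) -> list[int]:
        return self.table["position"].tolist()

    def _row(self, position: int) -> pd.Series:
        rows = self.table[self.table["position"] == position]
        if rows.empty:
            raise KeyError(
                f"position {position} is not exchange-competent for peptide "
                f"{self.peptide.id!r} (excluded: {self.excluded})"
            )
        return rows.iloc[0]

    def k_ch(self, position: int) -> float:
        return float(self._row(position)["k_ch"])

    def base_fraction(self, position: int) -> float:
        """Fraction of k_ch carried by base catalysis, in [0, 1]."""
        row = self._row(position)
        return float(row["k_base"] / row["k_ch"])

    def min_base_fraction(self) -> float:
        return float((self.table["k_base"] / self.table["k_ch"]).min())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["base_fraction"] = out["k_base"] / out["k_ch"]
        out.insert(1, "domain_position",
                   [self.peptide.domain_position(p) for p in out["position"]])
        out.to_csv(path, sep="\t", index=False, float_format="%.6e")


def compute_kch(peptide: PeptideSpec) -> IntrinsicRateTable:
    """Compute per-residue intrinsic D-to-H exchange rates for ``peptide``.

    Deterministic in the peptide spec; raises on unknown residue letters or
    a temperature outside [273 K, 373 K].
    """
    T = peptide.temperature
    if not 273.0 <= T <= 373.0:
        raise TemperatureRangeError(f"temperature {T:.1f} K outside [273 K, 373 K]")

    h_conc = 10.0 ** (-peptide.pH)
    oh_conc = 10.0 ** (peptide.pH - pkw(T))
    ka_ref = 10.0 ** LOG10_KA_REF * _arrhenius(EA_ACID, T)
    kb_ref = 10.0 ** LOG10_KB_REF * _arrhenius(EA_BASE, T)
    kw_ref = 10.0 ** LOG10_KW_REF * _arrhenius(EA_WATER, T)

    seq = peptide.sequence
    rows = []
    excluded = []
    for pos in range(1, len(seq) + 1):
        aa = seq[pos - 1]
        if pos <= 2 or aa == "P":
            excluded.append(pos)
            continue
        prev = seq[pos - 2]
        log_f_acid = (
            _titrated_factor(aa, "acid_lambda", h_conc, peptide.reduced_cys)
            + _titrated_factor(prev, "acid_rho", h_conc, peptide.reduced_cys)
        )
        log_f_base = (
            _titrated_factor(aa, "base_lambda", h_conc, peptide.reduced_cys)
            + _titrated_factor(prev, "base_rho", h_conc, peptide.reduced_cys)
        )
        k_acid = ka_ref * h_conc * 10.0 ** log_f_acid
        k_base = kb_ref * oh_conc * 10.0 ** log_f_base
        k_water = kw_ref * 10.0 ** log_f_base
        rows.append(
            {
                "position": pos,
                "residue": aa,
                "k_acid": k_acid,
                "k_base": k_base,
                "k_water": k_water,
                "k_ch": k_acid + k_base + k_water,
            }
        )
    return IntrinsicRateTable(peptide=peptide, table=pd.DataFrame(rows), excluded=excluded)


def base_fraction(table: IntrinsicRateTable, position: int) -> float:
    """Convenience wrapper for :meth:`IntrinsicRateTable.base_fraction`."""
    return table.base_fraction(position)


def ph_time_equivalent(t_min: float, ph_actual: float, ph_ref: float) -> float:
    """Map an incubation time at ``ph_actual`` to an effective time at ``ph_ref``.

    In the base-catalysis-dominated regime (pH >= 4) the intrinsic rate is
    proportional to [OH-], so a period ``t`` at one pH is kinetically
    equivalent to ``t * 10**(ph_actual - ph_ref)`` at the reference pH.  This
    is the pH-time equivalence used to emulate very short and very long
    incubations (e.g. 255 min at pH 6.45 stands in for ~5 d at pH 5).
    """
    if min(ph_actual, ph_ref) < BASE_DOMINANT_MIN_PH:
        warnings.warn(
            "pH below 4.0: base catalysis no longer dominates and the "
            "pH-time equivalence is unreliable",
            stacklevel=2,
        )
    return t_min * 10.0 ** (ph_actual - ph_ref)
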