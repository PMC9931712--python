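"""Linderstrom-Lang energetics: from slow-phase rates to H-bond opening dG.

Under EX2 conditions (H-bond reclosing much faster than chemical exchange)
and a predominantly closed state, the observed exchange rate of an amide
relates to the free energy change of opening its H-bond:

    dG = -R T ln( k_exp / (k_ch - k_exp) )

with R = 1.987e-3 kcal/(mol K).  For biphasic amides the slow phase is the
uncorrelated (EX2) component, so k_slow is always used.  The confidence
interval maps the +/- 1 standard error of log10 k_exp through the same
expression.  Amides whose observed rate reaches or exceeds k_ch violate the
EX2 assumption and are reported as not determined, never as a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import KineticFit
from .intrinsic import IntrinsicRateTable

R_KCAL = 1.987e-3  # kcal/(mol K)
_LN10 = np.log(10.0)

#: an amide must lose at least this fraction of its label over the observed
#: window for its rate (hence dG) to be considered determined
MIN_OBSERVABLE_DECAY = 0.05


class ExchangeRegimeError(ValueError):
    """k_exp >= k_ch: EX2 interpretation undefined."""


def delta_g(k_slow: float, k_ch: float, temperature: float) -> float:
    """Opening free energy in kcal/mol; requires 0 < k_slow < k_ch."""
    if not 0.0 < k_slow < k_ch:
        raise ExchangeRegimeError(
            f"k_slow={k_slow:.3g} outside (0, k_ch={k_ch:.3g}): EX2 assumption violated"
        )
    return float(-R_KCAL * temperature * np.log(k_slow / (k_ch - k_slow)))


def ci_delta_g(
    k_slow: float, se_log10_k_slow: float, k_ch: float, temperature: float
) -> tuple[float, float, list[str]]:
    """Standard confidence interval of dG from the +/-1 SE of log10 k_exp.

    Returns ``(ci_low, ci_high, flags)`` ordered so ci_low <= ci_high.  If
    the upper rate k_slow * 10**se reaches k_ch, the interval is one-sided
    (ci_low = -inf) and flagged.
    """
    flags: list[str] = []
    if not np.isfinite(se_log10_k_slow):
        raise ValueError("standard error of log10 k is not finite")
    k_hi = k_slow * 10.0 ** se_log10_k_slow
    k_lo = k_slow / 10.0 ** se_log10_k_slow
    hi = delta_g(k_lo, k_ch, temperature)  # slower rate -> larger dG
    if k_hi >= k_ch:
        flags.append("ci_lower_unbounded")
        lo = -np.inf
    else:
        lo = delta_g(k_hi, k_ch, temperature)
    return float(lo), float(hi), flags


@dataclass
class FlexibilityProfile:
    """Per-residue dG profile of one peptide, in domain numbering."""

    peptide_id: str
    temperature: float
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def build_profile(
    peptide,
    fits: dict[int, KineticFit | None],
    rates: IntrinsicRateTable,
    t_max: float | None = None,
) -> FlexibilityProfile:
    """Assemble the flexibility profile from fits and intrinsic rates.

    ``fits`` maps sequence positions to the selected :class:`KineticFit`
    (``None`` marks a fit failure / n.d. residue).  Positions present in the
    fits but absent from the rate table (or vice versa) indicate an upstream
    bookkeeping error and are reported together.

    Residues whose fitted slow rate is too small to have produced measurable
    exchange inside the observed window (k_slow * t_max below the detection
    threshold) are censored: their dG would be a lower bound only.
    """
    rate_positions = set(rates.positions())
    fit_positions = set(fits)
    orphans = sorted(rate_positions ^ fit_positions)
    if orphans:
        raise ValueError(
            f"position mismatch between fits and rate table; orphans: {orphans}"
        )

    k_det = MIN_OBSERVABLE_DECAY / t_max if t_max else 0.0

    rows = []
    for pos in sorted(fit_positions):
        fit = fits[pos]
        k_ch = rates.k_ch(pos)
        row = {
            "peptide_id": peptide.id,
            "position": pos,
            "domain_position": peptide.domain_position(pos),
            "delta_g_kcal_mol": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "biphasic": 0,
            "nd": 1,
            "reason": "",
        }
        if fit is None:
            row["reason"] = "fit_failure"
            rows.append(row)
            continue
        row["biphasic"] = int(fit.biphasic)
        if fit.k_slow < k_det:
            row["reason"] = "censored_slow_exchange"
            rows.append(row)
            continue
        try:
            dg = delta_g(fit.k_slow, k_ch, peptide.temperature)
        except ExchangeRegimeError:
            row["reason"] = "ex2_violated"
            rows.append(row)
            continue
        lo, hi, flags = ci_delta_g(fit.k_slow, fit.se_log10_k_slow, k_ch, peptide.temperature)
        row.update(
            delta_g_kcal_mol=dg, ci_low=lo, ci_high=hi, nd=0,
            reason=";".join(flags),
        )
        rows.append(row)
    return FlexibilityProfile(
        peptide_id=peptide.id, temperature=peptide.temperature, table=pd.DataFrame(rows)
    )


def heatmap_table(profile: FlexibilityProfile) -> pd.DataFrame:
    """Plotting-ready long table: dG color value plus marker columns.

    ``marker`` is ``diamond`` for biphasic amides and empty otherwise; n.d.
    rows carry NaN dG and ``nd=1`` so renderers can grey them out.
    """
    df = profile.table.copy()
    df["marker"] = np.where(df["biphasic"] == 1, "diamond", "")
    return df[
        ["peptide_id", "domain_position", "delta_g_kcal_mol", "biphasic", "nd", "marker"]
    ]


def plot_profile(profile: FlexibilityProfile, path) -> None:
    """Thin dG-vs-position rendering with CI bars and biphasic markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.table
    ok = df[df["nd"] == 0]
    fig, ax = plt.subplots(figsize=(7, 3))
    finite_lo = np.where(np.isfinite(ok["ci_low"]), ok["ci_low"], ok["delta_g_kcal_mol"])
    yerr = np.vstack(
        [ok["delta_g_kcal_mol"] - finite_lo, ok["ci_high"] - ok["delta_g_kcal_mol"]]
    )
    ax.errorbar(ok["domain_position"], ok["delta_g_kcal_mol"], yerr=yerr,
                fmt="o-", ms=4, lw=1, capsize=2)
    bi = ok[ok["biphasic"] == 1]
    ax.plot(bi["domain_position"], bi["delta_g_kcal_mol"], "D", ms=7,
            mfc="none", mec="crimson", label="biphasic")
    ax.set_xlabel("domain position")
    ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
    ax.set_title(profile.peptide_id)
    if len(bi):
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
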