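"""Opening free energies, confidence intervals, and profile assembly."""

import numpy as np
import pytest

from dhxflex.energetics import (
    ExchangeRegimeError,
    R_KCAL,
    build_profile,
    ci_delta_g,
    delta_g,
    heatmap_table,
)
from dhxflex.fitting import KineticFit, fit_mono, model_mono
from dhxflex.intrinsic import compute_kch
from dhxflex.peptide import PeptideSpec

from conftest import make_curve

T20 = 293.15


class TestDeltaG:
    def test_half_kch_gives_zero(self):
        assert delta_g(5.0, 10.0, T20) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        # k_ch = 10/min, k_exp = 0.01/min at 20 degC
        assert delta_g(0.01, 10.0, T20) == pytest.approx(4.02, abs=0.01)

    @pytest.mark.parametrize("k_slow", [0.0, -1.0, 10.0, 11.0])
    def test_regime_violations_raise(self, k_slow):
        with pytest.raises(ExchangeRegimeError):
            delta_g(k_slow, 10.0, T20)

    def test_strictly_decreasing_in_k_slow(self):
        ks = np.geomspace(1e-4, 9.99, 50)
        dgs = [delta_g(k, 10.0, T20) for k in ks]
        assert np.all(np.diff(dgs) < 0)


class TestConfidenceInterval:
    def test_zero_se_collapses(self):
        lo, hi, flags = ci_delta_g(0.01, 0.0, 10.0, T20)
        assert lo == hi == pytest.approx(delta_g(0.01, 10.0, T20))
        assert flags == []

    def test_small_rate_half_width(self):
        # for k_slow << k_ch the half width is ~ RT ln(10) * se
        lo, hi, _ = ci_delta_g(1e-4, 0.1, 10.0, T20)
        half = (hi - lo) / 2
        assert half == pytest.approx(R_KCAL * T20 * np.log(10) * 0.1, rel=0.01)

    def test_one_sided_when_upper_rate_reaches_kch(self):
        lo, hi, flags = ci_delta_g(9.0, 0.5, 10.0, T20)
        assert "ci_lower_unbounded" in flags
        assert lo == -np.inf and np.isfinite(hi)

    def test_coverage_near_one_sigma(self):
        """True dG inside the +/-1 SE interval in roughly 68% of replicates."""
        rng = np.random.default_rng(41)
        k_ch, dg_true = 5.0, 4.0
        k_true = k_ch * np.exp(-dg_true / (R_KCAL * T20)) / (
            1 + np.exp(-dg_true / (R_KCAL * T20))
        )
        t = np.geomspace(0.1, 10080, 12)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            y = model_mono(t, k_true) + rng.normal(0, 0.01, t.size)
            fit = fit_mono(make_curve(t, y))
            lo, hi, _ = ci_delta_g(fit.k_slow, fit.se_log10_k_slow, k_ch, T20)
            dg_t = delta_g(k_true, k_ch, T20)
            hits += lo <= dg_t <= hi
        assert 0.55 <= hits / n_rep <= 0.82


def _fit(k_slow, se=0.02, model="mono", degenerate=False):
    return KineticFit(
        model=model, k_slow=k_slow, k_fast=None if model == "mono" else 10 * k_slow,
        amp_slow=0.95 if model == "mono" else 0.475,
        amp_fast=0.0 if model == "mono" else 0.475,
        se_log10_k_slow=se, se_log10_k_fast=None, rss=1e-3, n_points=12,
        p_wilks=0.5 if model == "mono" else 1e-4, degenerate=degenerate,
    )


class TestBuildProfile:
    def _setup(self):
        pep = PeptideSpec(id="t", sequence="KAAAAAAK", numbering_offset=10)
        rates = compute_kch(pep)
        return pep, rates

    def test_all_mono_has_no_biphasic_flags(self):
        pep, rates = self._setup()
        fits = {p: _fit(rates.k_ch(p) * 1e-3) for p in rates.positions()}
        prof = build_profile(pep, fits, rates)
        assert prof.table["biphasic"].sum() == 0
        assert prof.table["nd"].sum() == 0
        assert list(prof.table["domain_position"]) == [
            p + 10 for p in rates.positions()
        ]

    def test_fit_failure_becomes_nd(self):
        pep, rates = self._setup()
        fits = {p: _fit(rates.k_ch(p) * 1e-3) for p in rates.positions()}
        fits[4] = None
        prof = build_profile(pep, fits, rates)
        row = prof.table.set_index("position").loc[4]
        assert row["nd"] == 1 and row["reason"] == "fit_failure"
        assert np.isnan(row["delta_g_kcal_mol"])

    def test_ex2_violation_becomes_nd(self):
        pep, rates = self._setup()
        fits = {p: _fit(rates.k_ch(p) * 1e-3) for p in rates.positions()}
        fits[5] = _fit(rates.k_ch(5) * 2.0)  # faster than chemistry: impossible
        prof = build_profile(pep, fits, rates)
        assert prof.table.set_index("position").loc[5, "reason"] == "ex2_violated"

    def test_censoring_of_unmeasurably_slow_exchange(self):
        pep, rates = self._setup()
        fits = {p: _fit(1e-9) for p in rates.positions()}
        prof = build_profile(pep, fits, rates, t_max=1e4)
        assert (prof.table["reason"] == "censored_slow_exchange").all()

    def test_position_mismatch_lists_orphans(self):
        pep, rates = self._setup()
        fits = {p: _fit(1e-3) for p in rates.positions()}
        del fits[3]
        fits[99] = _fit(1e-3)
        with pytest.raises(ValueError, match=r"\[3, 99\]"):
            build_profile(pep, fits, rates)

    def test_heatmap_table_marks_biphasic_with_diamonds(self):
        pep, rates = self._setup()
        fits = {p: _fit(rates.k_ch(p) * 1e-3) for p in rates.positions()}
        fits[6] = _fit(rates.k_ch(6) * 1e-3, model="bi")
        hm = heatmap_table(build_profile(pep, fits, rates))
        assert (hm.loc[hm["biphasic"] == 1, "marker"] == "diamond").all()
        assert (hm.loc[hm["biphasic"] == 0, "marker"] == "").all()
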