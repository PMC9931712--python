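"""Two-state exchange simulator: closed forms, regimes, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhxflex.energetics import R_KCAL, delta_g
from dhxflex.fitting import fit_bi
from dhxflex.fragments import ResidueExchangeCurve
from dhxflex.simulate import (
    DEFAULT_TIME_GRID,
    ex2_model,
    generate_dataset,
    get_preset,
    mixed_model,
    preset_names,
    slow_eigenvalue,
)

T20 = 293.15
rate = st.floats(1e-6, 1e6)


class TestSlowEigenvalue:
    @pytest.mark.parametrize("k_open, k_ch", [(0.1, 10.0), (10.0, 0.1), (1.0, 1.0)])
    def test_no_reclosing_limit(self, k_open, k_ch):
        assert slow_eigenvalue(k_open, 0.0, k_ch) == pytest.approx(min(k_open, k_ch))

    def test_ex2_limit(self):
        # k_close >> k_ch: lambda ~ k_open k_ch / k_close
        lam = slow_eigenvalue(1.0, 1000.0, 1.0)
        assert lam == pytest.approx(1e-3, rel=0.01)

    def test_ex1_limit(self):
        # k_close << k_ch: lambda ~ k_open
        lam = slow_eigenvalue(0.3, 0.001, 100.0)
        assert lam == pytest.approx(0.3, rel=0.01)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(k_open=rate, k_close=rate, k_ch=rate)
    def test_bounded_by_slowest_step(self, k_open, k_close, k_ch):
        lam = slow_eigenvalue(k_open, k_close, k_ch)
        assert 0 < lam <= min(k_open, k_ch) * (1 + 1e-12)

    def test_extreme_rate_ratios_stable(self):
        lam = slow_eigenvalue(1e-6, 1e6, 1e-6)
        assert np.isfinite(lam) and lam > 0


class TestResidueModels:
    @pytest.mark.parametrize("dg", [2.0, 4.0, 6.0])
    def test_ex2_model_dg_consistent_with_eq3(self, dg):
        """In the EX2 regime the slow eigenvalue mapped through the
        Linderstrom-Lang relation returns the construction dG within 0.05."""
        k_ch = 5.0
        m = ex2_model(dg, k_ch, T20)
        lam = m.eigenvalues()[0]
        assert delta_g(lam, k_ch, T20) == pytest.approx(dg, abs=0.05)

    def test_mixed_model_is_biphasic_with_separated_rates(self):
        m = mixed_model(3.5, 5.0, T20, fast_factor=100.0)
        lams = sorted(m.eigenvalues())
        assert m.biphasic
        assert lams[1] / lams[0] == pytest.approx(100.0, rel=0.1)

    def test_mixture_recovered_by_biexponential_fit(self):
        k_ch = 2.0
        m = mixed_model(3.5, k_ch, T20, fast_factor=100.0, w_fast=0.5)
        t = DEFAULT_TIME_GRID
        curve = ResidueExchangeCurve(
            position=5, times=t, d_mean=m.observable(t),
            d_sigma=np.full(t.size, 1e-4), n_fragments_used=np.full(t.size, 2),
        )
        fit = fit_bi(curve)
        lams = sorted(m.eigenvalues())
        assert fit.amp_slow == pytest.approx(0.475, abs=0.01)
        assert fit.amp_fast == pytest.approx(0.475, abs=0.01)
        assert fit.k_slow == pytest.approx(lams[0], rel=0.01)
        assert fit.k_fast == pytest.approx(lams[1], rel=0.01)


class TestGenerateDataset:
    def test_noiseless_ladder_differences_equal_residue_observables(self):
        spec = get_preset("rigid", seed=0, noise_sigma=0.0)
        data = generate_dataset(spec)
        frags = data["fragments"]
        n = len(spec.peptide)
        c = frags[frags.frag_type == "c"].pivot(
            index="time_min", columns="frag_index", values="deuterons"
        )
        for pos in range(4, n):
            diff = (c[pos] - c[pos - 1]).to_numpy()
            model = spec.residue_models[pos]
            np.testing.assert_allclose(diff, model.observable(spec.time_grid), atol=1e-12)

    def test_same_seed_byte_identical(self, tmp_path):
        spec1 = get_preset("hinge", seed=42)
        spec2 = get_preset("hinge", seed=42)
        generate_dataset(spec1, tmp_path / "a")
        generate_dataset(spec2, tmp_path / "b")
        for name in ("fragments.csv", "truth.tsv", "spec.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = generate_dataset(get_preset("hinge", seed=1))["fragments"]
        b = generate_dataset(get_preset("hinge", seed=2))["fragments"]
        assert not np.allclose(a["deuterons"], b["deuterons"])

    def test_truth_table_labels(self):
        spec = get_preset("hinge", seed=0)
        truth = generate_dataset(spec)["truth"]
        hinge = truth[(truth.domain_position >= 36) & (truth.domain_position <= 39)]
        core = truth[(truth.domain_position >= 40) & (truth.domain_position <= 50)]
        assert (hinge["biphasic_true"] == 1).all()
        assert (core["biphasic_true"] == 0).all()
        assert core["ex2_true"].all()
        assert core["dg_true"].between(3.9, 5.6).all()


class TestPresets:
    def test_names_enumerable(self):
        assert preset_names() == ["epsilon", "hinge", "rigid"]

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="epsilon"):
            get_preset("nope")

    def test_rigid_preset_uniform_high_stability(self):
        spec = get_preset("rigid", seed=0)
        truth = generate_dataset(spec)["truth"]
        core = truth[truth["position"].between(5, len(spec.peptide) - 2)]
        assert (core["biphasic_true"] == 0).all()
        assert core["dg_true"].round(6).eq(6.0).all()
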