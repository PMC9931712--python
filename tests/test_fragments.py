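"""Fragment-ladder processing: centroid arithmetic, smoothing, localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhxflex.fragments import (
    DELTA_MASS_DH,
    deuterons_from_centroid,
    residue_contents,
    smooth_ladder,
)
from dhxflex.peptide import PeptideSpec
from dhxflex.simulate import get_preset, generate_dataset, _per_residue_observables


class TestCentroid:
    @pytest.mark.parametrize(
        "offset, expected",
        [(0.0, 0.0), (3 * DELTA_MASS_DH, 3.0), (2.50, 2.484)],
    )
    def test_deuteron_count(self, offset, expected):
        assert deuterons_from_centroid(1000.0 + offset, 1000.0) == pytest.approx(
            expected, abs=1e-3
        )

    def test_warns_on_large_mass_deficit(self):
        with pytest.warns(UserWarning, match="below the fully protonated"):
            deuterons_from_centroid(999.0, 1000.0)


class TestSmoothLadder:
    def test_monotone_input_unchanged(self):
        y = np.array([0.5, 1.1, 1.1, 2.0])
        smoothed, flags = smooth_ladder(np.arange(2, 6), y)
        np.testing.assert_allclose(smoothed, y)
        assert flags == []

    def test_pool_adjacent_violators_average(self):
        smoothed, _ = smooth_ladder(
            np.array([2, 3, 4]), np.array([1.0, 0.8, 2.0]), np.ones(3)
        )
        np.testing.assert_allclose(smoothed, [0.9, 0.9, 2.0])

    def test_single_fragment_passthrough(self):
        smoothed, flags = smooth_ladder(np.array([4]), np.array([1.7]))
        assert smoothed.tolist() == [1.7]
        assert flags == ["single_fragment"]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=2, max_size=12),
    )
    def test_idempotent_and_monotone(self, values):
        idx = np.arange(2, 2 + len(values))
        once, _ = smooth_ladder(idx, np.array(values))
        twice, _ = smooth_ladder(idx, once)
        assert np.all(np.diff(once) >= -1e-12)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_smoothing_reduces_error_against_truth(self):
        rng = np.random.default_rng(3)
        truth = np.cumsum(rng.uniform(0.2, 1.0, size=15))
        mae_raw, mae_smooth = [], []
        for _ in range(50):
            noisy = truth + rng.normal(0, 0.15, truth.size)
            smoothed, _ = smooth_ladder(np.arange(2, 17), noisy)
            mae_raw.append(np.abs(noisy - truth).mean())
            mae_smooth.append(np.abs(smoothed - truth).mean())
        assert np.mean(mae_smooth) < np.mean(mae_raw)

    def test_preserves_total_content_at_noise_scale(self):
        rng = np.random.default_rng(4)
        truth = np.cumsum(rng.uniform(0.2, 1.0, size=12))
        sigma = 0.1
        noisy = truth + rng.normal(0, sigma, truth.size)
        smoothed, _ = smooth_ladder(np.arange(2, 14), noisy, np.full(truth.size, sigma))
        assert abs(smoothed[-1] - noisy[-1]) <= 2 * sigma


class TestResidueContents:
    def _frame(self, ftype, indices, values, t=1.0, sigma=0.01):
        import pandas as pd

        return pd.DataFrame(
            {
                "peptide_id": "t",
                "time_min": t,
                "frag_type": ftype,
                "frag_index": indices,
                "charge": 1,
                "deuterons": values,
                "sigma": sigma,
            }
        )

    def test_consecutive_differences(self):
        pep = PeptideSpec(id="t", sequence="AAAAA")
        frags = self._frame("c", [2, 3, 4], [1.0, 1.8, 2.8])
        curves = {c.position: c for c in residue_contents(frags, pep, min_points=1)}
        assert curves[3].d_mean[0] == pytest.approx(0.8)
        assert curves[4].d_mean[0] == pytest.approx(1.0)
        assert curves[5].times.size == 0  # no flanking pair on either side

    def test_noiseless_ladders_telescope_to_total(self):
        spec = get_preset("rigid", seed=0, noise_sigma=0.0)
        data = generate_dataset(spec)
        frags = data["fragments"]
        curves = residue_contents(frags, spec.peptide)
        n = len(spec.peptide)
        for t in spec.time_grid:
            total = frags[
                (frags.frag_type == "c") & (frags.frag_index == n - 1)
                & (frags.time_min == t)
            ]["deuterons"].iloc[0]
            # the largest c fragment covers amides 3..n-1; residue n is
            # reachable only from the z side
            summed = sum(
                c.d_mean[np.searchsorted(c.times, t)]
                for c in curves
                if c.times.size and c.position <= n - 1
            )
            assert summed == pytest.approx(total, abs=1e-9)

    def test_noiseless_round_trip_recovers_truth_exactly(self):
        spec = get_preset("hinge", seed=1, noise_sigma=0.0)
        truth = _per_residue_observables(spec)
        curves = residue_contents(generate_dataset(spec)["fragments"], spec.peptide)
        for c in curves:
            np.testing.assert_allclose(c.d_mean, truth[c.position], atol=1e-9)

    def test_noisy_round_trip_within_stated_uncertainty(self):
        spec = get_preset("hinge", seed=2, noise_sigma=0.01)
        truth = _per_residue_observables(spec)
        curves = residue_contents(generate_dataset(spec)["fragments"], spec.peptide)
        devs, within2 = [], []
        for c in curves:
            z = np.abs(c.d_mean - truth[c.position]) / c.d_sigma
            within2.extend(z <= 2.0)
            devs.extend(z)
        assert np.mean(within2) >= 0.93  # ~2 sigma coverage
        assert np.max(devs) < 5.0

    def test_uncovered_residue_marked_nd(self):
        spec = get_preset("rigid", seed=0, noise_sigma=0.0)
        frags = generate_dataset(spec)["fragments"]
        n = len(spec.peptide)
        # remove every fragment that would flank residue 10 on both sides,
        # at more than half of the time points
        drop_times = spec.time_grid[: 8]
        mask = ~(
            frags.time_min.isin(drop_times)
            & (
                ((frags.frag_type == "c") & frags.frag_index.isin([9, 10]))
                | ((frags.frag_type == "z") & frags.frag_index.isin([n - 10, n - 9]))
            )
        )
        curves = {c.position: c for c in residue_contents(frags[mask], spec.peptide)}
        assert "nd" in curves[10].flags
        assert "nd" not in curves[12].flags
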