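"""Merging-statistics tests: scaling, merging, R factors, CC1/2, DelAnom,
completeness and SmRmerge profiles, against hand arithmetic and analytic
expectations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from xtalmerge.core import PointGroup, UnitCell, unique_reflections
from xtalmerge.stats import (
    FrameProfile,
    cc_half,
    completeness,
    compute_stats,
    delanom,
    frame_profile,
    gaussian_smooth,
    merge,
    rmerge,
    rmerge_rmeas,
    scale_datasets,
)

from conftest import dataset_covering, make_dataset

BIGCELL = UnitCell(60.0, 60.0, 60.0)


def _flat_dataset(cid, rows):
    return make_dataset(cid, BIGCELL, rows)


def _many_reflection_datasets(n_refl, obs_fn, pg, seed=0, cid="a"):
    """One crystal observing the first n_refl unique reflections, with
    per-reflection observation values from obs_fn(rng, true_i)."""
    refl = unique_reflections(BIGCELL, pg, 3.0).head(n_refl)
    rng = np.random.default_rng(seed)
    true_i = rng.exponential(100.0, n_refl) + 1.0
    rows = []
    for (h, k, l), ti in zip(refl[["h", "k", "l"]].to_numpy(), true_i):
        for j, val in enumerate(obs_fn(rng, ti)):
            rows.append((j + 1, int(h), int(k), int(l), float(val), 1.0))
    return make_dataset(cid, BIGCELL, rows)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

class TestScaling:
    def _pair(self, factor):
        rows_a = [(1, 1, 0, 0, 10.0, 1.0), (1, 0, 1, 0, 20.0, 1.0), (1, 0, 0, 1, 40.0, 1.0)]
        rows_b = [(f, h, k, l, i * factor, s) for f, h, k, l, i, s in rows_a]
        return _flat_dataset("a", rows_a), _flat_dataset("b", rows_b)

    def test_identical_datasets_scale_to_unity(self, pg1):
        a, b = self._pair(1.0)
        ss = scale_datasets([a, b], pg1, 2.0)
        assert ss.reference == "a"
        assert ss["a"] == 1.0 and ss["b"] == pytest.approx(1.0)

    def test_doubled_intensities_get_half_scale(self, pg1):
        a, b = self._pair(2.0)
        ss = scale_datasets([a, b], pg1, 2.0)
        assert ss["b"] == pytest.approx(0.5)

    def test_three_dataset_geometric_ladder(self, pg1):
        a, b = self._pair(2.0)
        rows_c = [(f, h, k, l, i * 2, s) for f, h, k, l, i, s in b.observations.assign(crystal_id="c")[
            ["frame", "h", "k", "l", "intensity", "sigma"]].itertuples(index=False)]
        c = _flat_dataset("c", rows_c)
        ss = scale_datasets([a, b, c], pg1, 2.0)
        assert (ss["a"], ss["b"], ss["c"]) == pytest.approx((1.0, 0.5, 0.25))

    def test_empty_input_rejected(self, pg1):
        with pytest.raises(ValueError):
            scale_datasets([], pg1, 2.0)

    def test_disjoint_dataset_warns_and_keeps_unit_scale(self, pg1):
        a = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0)])
        b = _flat_dataset("b", [(1, 0, 2, 0, 10.0, 1.0)])
        with pytest.warns(UserWarning, match="shares no reflections"):
            ss = scale_datasets([a, b], pg1, 2.0)
        assert ss["b"] == 1.0


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

class TestMerge:
    def test_single_observation_passthrough(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 2, 3, 10.0, 2.0)])
        m = merge([ds], pg1, 2.0)
        row = m.table.iloc[0]
        assert (row["i"], row["sig"], row["mult"]) == pytest.approx((10.0, 2.0, 1))

    def test_equal_sigma_symmetric_mean(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 2, 3, 10.0, 1.0), (2, 1, 2, 3, 12.0, 1.0)])
        m = merge([ds], pg1, 2.0)
        assert m.table.iloc[0]["i"] == pytest.approx(11.0)

    def test_inverse_variance_weighted_mean(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 2, 3, 10.0, 1.0), (2, 1, 2, 3, 20.0, 2.0)])
        m = merge([ds], pg1, 2.0)
        assert m.table.iloc[0]["i"] == pytest.approx(12.0)
        assert m.table.iloc[0]["sig"] == pytest.approx(1.0 / math.sqrt(1.0 + 0.25))

    def test_friedel_mates_separate_in_anomalous_mode(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 2, 3, 10.0, 1.0), (1, -1, -2, -3, 6.0, 1.0)])
        plain = merge([ds], pg1, 2.0)
        anom = merge([ds], pg1, 2.0, anomalous=True)
        assert len(plain.table) == 1 and plain.table.iloc[0]["mult"] == 2
        assert len(anom.table) == 2
        by_sign = anom.table.set_index("sign")["i"]
        assert by_sign[1] == pytest.approx(10.0) and by_sign[-1] == pytest.approx(6.0)

    def test_permutation_invariance(self, pg222):
        rows = [(1, 1, 2, 3, 10.0, 1.0), (2, -1, 2, 3, 12.0, 2.0), (1, 2, 0, 1, 5.0, 1.0)]
        m1 = merge([_flat_dataset("a", rows)], pg222, 2.0)
        m2 = merge([_flat_dataset("a", rows[::-1])], pg222, 2.0)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_resolution_cutoff_applied(self, pg1):
        cell = UnitCell(10, 10, 10)
        ds = make_dataset("a", cell, [(1, 1, 0, 0, 10.0, 1.0), (1, 4, 4, 4, 5.0, 1.0)])
        m = merge([ds], pg1, 3.0)  # d(444) = 1.44 A: excluded
        assert len(m.table) == 1 and tuple(m.table.iloc[0][["h", "k", "l"]]) == (1, 0, 0)


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

class TestRmerge:
    def test_identical_repeats_give_zero(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0), (2, 1, 0, 0, 10.0, 1.0),
                                 (1, 0, 1, 0, 4.0, 1.0), (2, 0, 1, 0, 4.0, 1.0)])
        assert rmerge([ds], pg1, 2.0) == pytest.approx(0.0)

    def test_two_observation_hand_value(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0), (2, 1, 0, 0, 12.0, 1.0)])
        r_merge, r_meas = rmerge_rmeas([ds], pg1, 2.0)
        assert r_merge == pytest.approx(2.0 / 22.0)
        assert r_meas == pytest.approx(2.0 / 22.0 * math.sqrt(2.0))

    def test_no_repeats_is_undefined_not_zero(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0), (1, 0, 1, 0, 12.0, 1.0)])
        assert rmerge_rmeas([ds], pg1, 2.0) == (None, None)

    def test_symmetry_mates_pool_into_one_reflection(self, pg222):
        # (1,2,3) and (-1,2,3) are 222-equivalent under Friedel: one group
        ds = _flat_dataset("a", [(1, 1, 2, 3, 10.0, 1.0), (1, -1, 2, 3, 12.0, 1.0)])
        assert rmerge([ds], pg222, 2.0) == pytest.approx(2.0 / 22.0)


# ---------------------------------------------------------------------------
# CC1/2
# ---------------------------------------------------------------------------

class TestCCHalf:
    def test_noise_free_data_gives_unity_for_any_seed(self, pg1):
        ds = _many_reflection_datasets(50, lambda rng, ti: [ti, ti, ti, ti], pg1)
        values = [cc_half([ds], pg1, 3.0, seed=s) for s in range(20)]
        assert all(v == pytest.approx(1.0) for v in values)

    def test_pure_noise_decorrelates(self, pg1):
        ds = _many_reflection_datasets(600, lambda rng, ti: rng.normal(0, 1, 4), pg1, seed=5)
        cc = cc_half([ds], pg1, 3.0, seed=1)
        assert abs(cc) < 3.0 / math.sqrt(600)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_variance_ratio_expectation(self, pg1, seed):
        """Additive model: cc_half ~ sig_s^2 / (sig_s^2 + sig_eps^2)."""
        sig_s, sig_eps = 10.0, 10.0  # per-half noise sd (one obs per half)
        ds = _many_reflection_datasets(
            2000,
            lambda rng, ti: ti + rng.normal(0, sig_eps, 2),
            pg1,
            seed=seed,
        )
        # signal variance of the planted exponential(100) truth
        expected = 100.0**2 / (100.0**2 + sig_eps**2)
        cc = cc_half([ds], pg1, 3.0, seed=seed + 10)
        assert cc == pytest.approx(expected, abs=0.05)

    def test_too_few_reflections_undefined(self, pg1):
        ds = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0), (2, 1, 0, 0, 12.0, 1.0)])
        assert cc_half([ds], pg1, 2.0) is None

    def test_seeded_reproducibility(self, pg1):
        ds = _many_reflection_datasets(200, lambda rng, ti: ti + rng.normal(0, 5, 3), pg1)
        assert cc_half([ds], pg1, 3.0, seed=42) == cc_half([ds], pg1, 3.0, seed=42)
        assert cc_half([ds], pg1, 3.0, seed=42) != cc_half([ds], pg1, 3.0, seed=43)


# ---------------------------------------------------------------------------
# DelAnom
# ---------------------------------------------------------------------------

def _bijvoet_dataset(n_refl, danom_fn, noise_sd, pg, seed=0):
    refl = unique_reflections(BIGCELL, pg, 3.0).head(n_refl)
    rng = np.random.default_rng(seed)
    true_i = rng.exponential(100.0, n_refl) + 5.0
    rows = []
    for (h, k, l), ti in zip(refl[["h", "k", "l"]].to_numpy(), true_i):
        dan = danom_fn(rng, ti)
        for j in range(2):
            rows.append((1, int(h), int(k), int(l),
                         ti + dan / 2 + rng.normal(0, noise_sd), 1.0))
            rows.append((1, int(-h), int(-k), int(-l),
                         ti - dan / 2 + rng.normal(0, noise_sd), 1.0))
    return make_dataset("a", BIGCELL, rows)


class TestDelAnom:
    def test_planted_noise_free_signal_gives_unity(self, pg1):
        ds = _bijvoet_dataset(60, lambda rng, ti: 0.3 * ti, 0.0, pg1)
        assert delanom([ds], pg1, 3.0, seed=4) == pytest.approx(1.0)

    def test_zero_signal_noisy_data_decorrelates(self, pg1):
        ds = _bijvoet_dataset(600, lambda rng, ti: 0.0, 5.0, pg1, seed=2)
        val = delanom([ds], pg1, 3.0, seed=8)
        assert abs(val) < 3.0 / math.sqrt(600)

    def test_too_few_pairs_undefined(self, pg1):
        ds = _bijvoet_dataset(2, lambda rng, ti: 0.1 * ti, 0.0, pg1)
        assert delanom([ds], pg1, 3.0) is None

    def test_single_mate_reflections_excluded(self, pg1):
        # only I(+) measured: no Bijvoet pairs at all
        ds = _many_reflection_datasets(20, lambda rng, ti: [ti, ti], pg1)
        assert delanom([ds], pg1, 3.0) is None


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

class TestCompleteness:
    def test_full_and_half_coverage(self, cubic10, pg222):
        refl = unique_reflections(cubic10, pg222, 2.5)
        rng = np.random.default_rng(0)
        intensities = rng.exponential(100, len(refl)) + 1
        full = dataset_covering("a", cubic10, refl, intensities, n_copies=1)
        m_full = merge([full], pg222, 2.5)
        assert completeness(m_full, cubic10, pg222, 2.5) == pytest.approx(100.0)
        half = dataset_covering("b", cubic10, refl.iloc[::2], intensities[::2], n_copies=1)
        m_half = merge([half], pg222, 2.5)
        expected = 100.0 * len(refl.iloc[::2]) / len(refl)
        assert completeness(m_half, cubic10, pg222, 2.5) == pytest.approx(expected)

    def test_matches_brute_force_ratio_on_random_cells(self):
        """Property: completeness == 100 * |subset| / brute-force unique count."""
        rng = np.random.default_rng(123)
        names = ["1", "2", "222", "4"]
        for trial in range(50):
            name = names[trial % len(names)]
            a, b, c = rng.uniform(6, 12), rng.uniform(6, 12), rng.uniform(6, 12)
            # the cell must be compatible with the point group's metric
            cell = UnitCell(a, a, c) if name == "4" else UnitCell(a, b, c)
            pg = PointGroup.from_name(name)
            dmin = rng.uniform(2.5, 4.0)
            refl = unique_reflections(cell, pg, dmin)
            if len(refl) < 2:
                continue
            keep = rng.random(len(refl)) < rng.uniform(0.3, 1.0)
            if not keep.any():
                continue
            sub = refl.loc[keep]
            ds = dataset_covering("a", cell, sub, np.full(len(sub), 50.0), n_copies=1)
            m = merge([ds], pg, dmin)
            val = completeness(m, cell, pg, dmin)
            assert val == pytest.approx(100.0 * keep.sum() / len(refl))
            assert val <= 100.0

    def test_empty_resolution_shell_rejected(self, cubic10, pg1):
        ds = make_dataset("a", cubic10, [(1, 1, 0, 0, 10.0, 1.0)])
        m = merge([ds], pg1, 2.5)
        with pytest.raises(ValueError):
            completeness(m, cubic10, pg1, 11.0)


# ---------------------------------------------------------------------------
# SmRmerge profiles
# ---------------------------------------------------------------------------

class TestFrameProfile:
    def test_smoothing_preserves_constants(self):
        raw = np.full(30, 0.1)
        assert gaussian_smooth(raw, 2.0) == pytest.approx(raw)

    def test_degenerate_kernel_returns_raw(self):
        raw = np.array([0.1, 0.5, 0.2, np.nan, 0.3])
        out = gaussian_smooth(raw, 0.0)
        np.testing.assert_array_equal(np.isnan(out), np.isnan(raw))
        assert out[[0, 1, 2, 4]] == pytest.approx(raw[[0, 1, 2, 4]])

    def test_spike_flattens_and_spreads(self):
        """7-frame fixture: direct kernel arithmetic around a single spike."""
        raw = np.array([0.1, 0.1, 0.1, 1.0, 0.1, 0.1, 0.1])
        out = gaussian_smooth(raw, 1.0)
        assert out[3] < raw[3]
        assert out[2] > 0.1 and out[4] > 0.1
        # oracle: renormalised truncated kernel at the spike position
        off = np.arange(-3, 4)
        w = np.exp(-0.5 * off**2)
        assert out[3] == pytest.approx(float(np.sum(w * raw)) / float(np.sum(w)))

    def test_undefined_frames_stay_undefined_and_are_skipped(self):
        raw = np.array([0.1, np.nan, 0.3])
        out = gaussian_smooth(raw, 1.0)
        assert np.isnan(out[1])
        # neighbours smooth over defined frames only (weights renormalised)
        w0 = np.exp(-0.5 * np.array([0.0, 4.0]))  # offsets 0, +2 from frame 1
        assert out[0] == pytest.approx((0.1 * w0[0] + 0.3 * w0[1]) / w0.sum())

    def test_mean_preserved_on_fully_defined_trace(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0.05, 0.3, 64)
        out = gaussian_smooth(raw, 2.0)
        assert out.mean() == pytest.approx(raw.mean(), rel=0.02)

    def test_raw_values_against_reference(self, pg1):
        # two frames: frame 1 matches the reference, frame 2 is 20% high
        ref_rows = [(1, 1, 0, 0, 10.0, 1.0), (1, 0, 1, 0, 20.0, 1.0)]
        ref = merge([_flat_dataset("r", ref_rows)], pg1, 2.0)
        ds = _flat_dataset("a", [(1, 1, 0, 0, 10.0, 1.0), (1, 0, 1, 0, 20.0, 1.0),
                                 (2, 1, 0, 0, 12.0, 1.0), (2, 0, 1, 0, 24.0, 1.0)])
        prof = frame_profile(ds, ref, kernel_sigma=0.0)
        assert prof.raw[0] == pytest.approx(0.0)
        assert prof.raw[1] == pytest.approx((2.0 + 4.0) / 30.0)

    def test_unmatchable_crystal_gets_all_undefined_profile(self, pg1):
        ref = merge([_flat_dataset("r", [(1, 1, 0, 0, 10.0, 1.0)])], pg1, 2.0)
        ds = _flat_dataset("a", [(1, 0, 5, 0, 3.0, 1.0)])
        prof = frame_profile(ds, ref)
        assert np.isnan(prof.raw).all() and np.isnan(prof.smoothed).all()


def test_compute_stats_bundle_consistency(pg222, cubic10):
    refl = unique_reflections(cubic10, pg222, 2.5)
    rng = np.random.default_rng(2)
    intensities = rng.exponential(100, len(refl)) + 1
    ds = dataset_covering("a", cubic10, refl, intensities, n_copies=2)
    merged, bundle = compute_stats([ds], pg222, cubic10, 2.5, seed=0)
    assert bundle.rmerge == pytest.approx(0.0)
    assert bundle.cc_half == pytest.approx(1.0)
    assert bundle.completeness == pytest.approx(100.0)
    assert bundle.mean_multiplicity == pytest.approx(2.0)
    assert bundle.n_unique == len(refl)
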