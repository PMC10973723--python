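"""Signal-processing chain: AsLS baseline, integration, IQR filter, normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediaopt.design import M9_REFERENCE, MediaComposition
from mediaopt.ms_processing import (
    AbundanceTable,
    AsLSConfig,
    asls_baseline,
    integrate_area,
    iqr_filter,
    normalise_to_m9,
    process_plate,
)
from mediaopt.synthetic_data import InjectionTrace, NoiseSpec, TraceSpec, simulate_plate

QUIET = NoiseSpec(replicate_cv=0.0, heteroskedastic_slope=0.0, outlier_prob=0.0)
CLEAN = TraceSpec(drift_frac=0.0, white_noise_frac=0.0)


def _trace(y, t=None):
    y = np.asarray(y, float)
    t = np.linspace(0, 1, y.size) if t is None else np.asarray(t, float)
    return InjectionTrace(well="A1", metabolite="m", times=t, intensities=y)


class TestAsLSBaseline:
    def test_zero_signal_zero_baseline(self):
        z = asls_baseline(np.zeros(50))
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_constant_signal_is_its_own_baseline(self):
        c = 7.5
        z = asls_baseline(np.full(80, c))
        assert np.allclose(z, c, atol=1e-6 * c)

    def test_recovers_linear_drift_away_from_peak(self):
        t = np.linspace(0, 1, 121)
        drift = 100.0 + 50.0 * t
        peak = 10.0 * 50.0 * np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2)
        z = asls_baseline(drift + peak, AsLSConfig())
        far = np.abs(t - 0.3) > 3 * 0.02
        rel = np.abs(z[far] - drift[far]) / np.ptp(drift)
        assert rel.max() < 0.02

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 121)
        y = 50 * t + 200 * np.exp(-0.5 * ((t - 0.3) / 0.05) ** 2) + rng.normal(0, 1, t.size)
        z1 = asls_baseline(y)
        z2 = asls_baseline(y + 123.0)
        assert np.allclose(z2, z1 + 123.0, atol=1e-6 * np.ptp(y))

    def test_rejects_non_finite_and_short_input(self):
        with pytest.raises(ValueError):
            asls_baseline(np.array([1.0, np.nan, 2.0]))
        with pytest.raises(ValueError):
            asls_baseline(np.array([1.0, 2.0]))


class TestIntegrateArea:
    def test_constant_unit_signal(self):
        assert integrate_area(_trace(np.ones(11))) == pytest.approx(1.0)

    def test_triangular_peak_exact(self):
        # height 2, base 0.5 min, nodes at the vertices: area = 0.5
        t = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.array([0.0, 2.0, 0.0, 0.0, 0.0])
        tr = _trace(y, np.array([0.0, 0.25, 0.5, 0.75, 1.0]))
        assert integrate_area(tr) == pytest.approx(0.5)

    def test_gaussian_matches_analytic_area(self):
        t = np.linspace(0, 1, 600)
        sigma, area = 0.05, 3.7
        y = area * np.exp(-0.5 * ((t - 0.4) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        assert integrate_area(_trace(y, t)) == pytest.approx(area, rel=1e-4)

    def test_baseline_subtracted_without_clipping(self):
        y = np.full(11, 2.0)
        base = np.full(11, 3.0)  # negative residual must be preserved
        assert integrate_area(_trace(y), base) == pytest.approx(-1.0)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            integrate_area(_trace(np.array([1.0]), np.array([0.0])))


class TestIQRFilter:
    def test_all_equal_all_kept(self):
        assert iqr_filter([3.0] * 6).all()

    def test_documented_example(self):
        # median 3, Q1 2, Q3 4 under linear interpolation -> bounds [0, 6]
        mask = iqr_filter([1, 2, 3, 4, 100])
        assert mask.tolist() == [True, True, True, True, False]

    def test_small_group_bypass(self):
        assert iqr_filter([1.0, 2.0, 1000.0]).all()

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=30))
    def test_matches_brute_force_oracle(self, values):
        v = np.asarray(values)
        mask = iqr_filter(v)
        med = np.median(v)
        q1, q3 = np.percentile(v, [25, 75])
        expected = [(med - 1.5 * (q3 - q1)) <= x <= (med + 1.5 * (q3 - q1)) for x in v]
        assert mask.tolist() == expected

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30), st.integers(0, 10))
    def test_idempotent_on_kept_subset(self, values, _seed):
        v = np.asarray(values)
        kept = v[iqr_filter(v)]
        if kept.size >= 4:
            med = np.median(kept)
            q1, q3 = np.percentile(kept, [25, 75])
            if (kept >= med - 1.5 * (q3 - q1)).all() and (kept <= med + 1.5 * (q3 - q1)).all():
                assert iqr_filter(kept).all()


class TestNormalisation:
    def _table(self, layout, areas):
        df = pd.DataFrame({"m": areas}, index=[w.well for w in layout.wells])
        return AbundanceTable(data=df, batch="b0")

    def test_m9_reference_mean_is_one(self, small_layout):
        rng = np.random.default_rng(0)
        areas = rng.uniform(10, 100, len(small_layout.wells))
        rel = normalise_to_m9(self._table(small_layout, areas), small_layout)
        m9_wells = [w.well for w in small_layout.wells_of(M9_REFERENCE)]
        assert rel.data.loc[m9_wells, "m"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_group_mean_oracle(self, small_layout):
        rng = np.random.default_rng(1)
        areas = rng.uniform(10, 100, len(small_layout.wells))
        table = self._table(small_layout, areas)
        rel = normalise_to_m9(table, small_layout)
        m9_wells = [w.well for w in small_layout.wells_of(M9_REFERENCE)]
        ref = np.mean([table.data.loc[w, "m"] for w in m9_wells])
        for w in small_layout.wells:
            expected = table.data.loc[w.well, "m"] / ref
            assert rel.data.loc[w.well, "m"] == pytest.approx(expected, abs=1e-12)

    def test_scaling_invariance(self, small_layout):
        rng = np.random.default_rng(2)
        areas = rng.uniform(10, 100, len(small_layout.wells))
        r1 = normalise_to_m9(self._table(small_layout, areas), small_layout)
        r2 = normalise_to_m9(self._table(small_layout, areas * 7.3), small_layout)
        assert np.allclose(r1.data.to_numpy(), r2.data.to_numpy())

    def test_error_names_batch_and_metabolite(self, small_layout):
        table = self._table(small_layout, np.ones(len(small_layout.wells)))
        m9_wells = [w.well for w in small_layout.wells_of(M9_REFERENCE)]
        table.kept.loc[m9_wells, "m"] = False
        with pytest.raises(ValueError, match="b0.*'m'"):
            normalise_to_m9(table, small_layout)


class TestProcessPlate:
    def test_zero_noise_end_to_end_recovery(self, small_layout, landscape):
        traces = simulate_plate(small_layout, {"surfactin_C": landscape}, QUIET, seed=0, trace=CLEAN)
        rel = process_plate(traces, small_layout)
        for w in small_layout.wells:
            if w.composition is None:
                continue
            comp = MediaComposition(0.4, 18.7) if w.treatment == M9_REFERENCE else w.composition
            assert rel.data.loc[w.well, "surfactin_C"] == pytest.approx(landscape.at(comp), rel=1e-3)

    def test_injected_outlier_removed(self, small_layout, landscape):
        traces = simulate_plate(small_layout, {"surfactin_C": landscape}, QUIET, seed=0, trace=CLEAN)
        victim = small_layout.wells_of("combination_1")[0].well
        for t in traces:
            if t.well == victim:
                t.intensities = t.intensities * 10.0
        rel = process_plate(traces, small_layout)
        assert not rel.kept.loc[victim, "surfactin_C"]
        others = [w.well for w in small_layout.wells_of("combination_1") if w.well != victim]
        truth = landscape.at(small_layout.composition_of("combination_1"))
        assert rel.data.loc[others, "surfactin_C"].mean() == pytest.approx(truth, rel=0.05)

    def test_empty_trace_set_gives_empty_table(self, small_layout):
        rel = process_plate([], small_layout)
        assert rel.data.empty

    def test_condition_stats_counts_replicates(self, small_layout, landscape):
        traces = simulate_plate(small_layout, {"surfactin_C": landscape}, QUIET, seed=0, trace=CLEAN)
        rel = process_plate(traces, small_layout)
        stats = rel.condition_stats(small_layout, "surfactin_C")
        assert set(stats["n"]) == {6}
        assert len(stats) == 8  # 7 combinations + M9 reference; control excluded

    def test_drift_corrected_recovery_within_two_percent(self, small_layout, landscape):
        drifty = TraceSpec(drift_frac=0.05, white_noise_frac=0.0)
        traces = simulate_plate(small_layout, {"surfactin_C": landscape}, QUIET, seed=3, trace=drifty)
        rel = process_plate(traces, small_layout)
        for w in small_layout.wells:
            if w.composition is None or w.treatment == M9_REFERENCE:
                continue
            truth = landscape.at(w.composition)
            assert rel.data.loc[w.well, "surfactin_C"] == pytest.approx(truth, rel=0.06)
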