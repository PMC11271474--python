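import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rodfission.divsite import (
    AnalysisConfig,
    DivisionRecord,
    DivisionSiteModel,
    MeasurementRecord,
    assign_fraction_class,
    canonical_fraction_sets,
    classify_records,
    compare_division_models,
    estimate_density_modes,
    fit_class_lines,
    mirror_sites,
    relative_division_site,
)
from rodfission.errors import ConfigurationError, ValidationError
from rodfission.popgen import make_reference_measurements

positive = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)


def _rec(d1, d2, cid="x"):
    return MeasurementRecord(cell_id=cid, replicate="r1", d1=d1, d2=d2)


class TestRelativeDivisionSite:
    @pytest.mark.parametrize("d1,d2,L,daughter,S", [
        (1.0, 1.0, 2.0, 1.0, 0.5),
        (2.0, 4.0, 6.0, 2.0, 1 / 3),
        (1.5, 4.5, 6.0, 1.5, 0.25),
    ])
    def test_arithmetic(self, d1, d2, L, daughter, S):
        rec = relative_division_site(_rec(d1, d2))
        assert rec.L_mother == pytest.approx(L)
        assert rec.L_daughter == pytest.approx(daughter)
        assert rec.S == pytest.approx(S)

    @given(d1=positive, d2=positive)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_range(self, d1, d2):
        a = relative_division_site(_rec(d1, d2))
        b = relative_division_site(_rec(d2, d1))
        assert a.S == b.S
        assert 0 < a.S <= 0.5
        assert a.L_daughter <= a.L_mother / 2

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValidationError):
            _rec(0.0, 2.0)
        with pytest.raises(ValidationError):
            _rec(1.0, -1.0)


class TestMirroring:
    def test_midcell_point_keeps_unit_weight(self):
        rec = relative_division_site(_rec(1.0, 1.0))
        m = mirror_sites([rec])
        assert list(m["s"]) == [0.5]
        assert list(m["weight"]) == [1.0]

    def test_asymmetric_point_splits_weight(self):
        rec = relative_division_site(_rec(1.5, 4.5))
        m = mirror_sites([rec])
        assert sorted(m["s"]) == pytest.approx([0.25, 0.75])
        assert list(m["weight"]) == [0.5, 0.5]

    def test_total_weight_is_record_count(self, reference_measurements):
        _, meas = reference_measurements
        records = [relative_division_site(r) for r in meas]
        assert mirror_sites(records)["weight"].sum() == pytest.approx(len(records))

    def test_mirrored_kde_symmetric_about_half(self, reference_measurements):
        _, meas = reference_measurements
        m = mirror_sites([relative_division_site(r) for r in meas])
        kde = stats.gaussian_kde(m["s"], bw_method="silverman",
                                 weights=m["weight"])
        grid = np.linspace(0.01, 0.99, 197)
        assert np.max(np.abs(kde(grid) - kde(1 - grid))) < 1e-9


class TestFractionAssignment:
    @pytest.mark.parametrize("S,L,expected", [
        (0.48, 2.0, "1/2"),
        (0.34, 6.0, "1/3"),
        (0.26, 9.0, "1/4"),
        (0.45, 6.0, "1/2"),
        (0.30, 9.0, "1/3"),
    ])
    def test_nearest_allowed_fraction(self, S, L, expected):
        rec = DivisionRecord("x", L_mother=L, L_daughter=S * L, S=S)
        assert assign_fraction_class(rec) == expected

    def test_tie_goes_to_more_symmetric_fraction(self):
        S = (1 / 3 + 1 / 2) / 2  # equidistant between 1/3 and 1/2
        rec = DivisionRecord("x", L_mother=6.0, L_daughter=S * 6.0, S=S)
        assert assign_fraction_class(rec) == "1/2"

    def test_matches_brute_force_on_random_pairs(self):
        # exhaustive nearest-fraction recount, independent of the implementation
        cfg = AnalysisConfig()
        rng = np.random.default_rng(12)
        S = rng.uniform(0.01, 0.5, 10000)
        L = rng.uniform(0.5, 15.0, 10000)
        for s, length in zip(S, L):
            cls = ("short" if length <= 5 else "mid" if length <= 8 else "long")
            allowed = cfg.allowed_fractions[cls]
            dists = [(abs(s - f), -f, f) for f in allowed]
            dists.sort()
            brute = dists[0][2]
            rec = DivisionRecord("x", L_mother=length, L_daughter=s * length, S=s)
            got = assign_fraction_class(rec, cfg)
            label = {0.5: "1/2", 1 / 3: "1/3", 0.25: "1/4"}[brute]
            assert got == label


class TestClassLines:
    def test_constant_class_has_zero_sd(self):
        records = classify_records([
            relative_division_site(_rec(2.0, 4.0, f"c{i}")) for i in range(5)
        ])
        table = fit_class_lines(records)
        row = table[table["fraction_class"] == "1/3"].iloc[0]
        assert row["slope"] == pytest.approx(1 / 3)
        assert row["sd"] == pytest.approx(0.0)

    def test_single_record_slope(self):
        rec = DivisionRecord("x", 10.0, 2.7, 0.27, fraction_class="1/4")
        table = fit_class_lines([rec])
        assert table.iloc[0]["slope"] == pytest.approx(0.27)

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            fit_class_lines([])

    def test_class_slopes_recover_generator_fractions(self, reference_measurements):
        _, meas = reference_measurements
        records = classify_records([relative_division_site(r) for r in meas])
        table = fit_class_lines(records).set_index("fraction_class")
        assert table.loc["1/2", "slope"] == pytest.approx(0.5, abs=0.02)
        assert table.loc["1/3", "slope"] == pytest.approx(1 / 3, abs=0.02)
        assert table.loc["1/4", "slope"] == pytest.approx(0.25, abs=0.02)


class TestDensityModes:
    def test_single_midcell_mode(self):
        rng = np.random.default_rng(3)
        s = np.clip(rng.normal(0.5, 0.02, 200), 0.02, 0.98)
        m = pd.DataFrame({"s": s, "weight": 1.0, "L_mother": 2.0,
                          "cell_id": "x"})
        out = estimate_density_modes(m)
        assert len(out["modes"]) == 1
        assert out["modes"][0] == pytest.approx(0.5, abs=0.02)

    def test_three_class_modes(self, reference_measurements):
        _, meas = reference_measurements
        mirrored = mirror_sites([relative_division_site(r) for r in meas])
        modes = estimate_density_modes(mirrored)["modes"]
        for target in (1 / 3, 0.5, 2 / 3):
            assert min(abs(m - target) for m in modes) <= 0.02

    def test_uniform_sample_has_no_modes_in_most_runs(self):
        # Monte-Carlo calibration: featureless data should not report modes
        no_mode = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            m = pd.DataFrame({"s": rng.uniform(0.01, 0.99, 300),
                              "weight": 1.0, "L_mother": 2.0, "cell_id": "x"})
            no_mode += not estimate_density_modes(m)["modes"]
        assert no_mode >= 0.9 * n_runs

    def test_too_few_points_raises(self):
        m = pd.DataFrame({"s": [0.4, 0.5], "weight": [1.0, 1.0],
                          "L_mother": [2.0, 2.0], "cell_id": ["a", "b"]})
        with pytest.raises(ValidationError):
            estimate_density_modes(m)

    def test_histogram_uses_fixed_bin_width(self, reference_measurements):
        _, meas = reference_measurements
        mirrored = mirror_sites([relative_division_site(r) for r in meas])
        hist = estimate_density_modes(mirrored)["histogram"]
        widths = hist["bin_right"] - hist["bin_left"]
        assert np.allclose(widths, 0.02)
        assert hist["weight"].sum() == pytest.approx(len(meas))


class TestCanonicalFractions:
    @pytest.mark.parametrize("m,expected", [
        (1, {0.5}),
        (2, {0.25, 0.75}),
        (3, {1 / 6, 0.5, 5 / 6}),
        (4, {1 / 8, 3 / 8, 5 / 8, 7 / 8}),
    ])
    def test_min_system_sets(self, m, expected):
        assert canonical_fraction_sets("min_system", m) == expected

    def test_odd_fraction_sets_mirror_symmetric(self):
        for cls in ("short", "mid", "long"):
            fr = canonical_fraction_sets("odd_fraction", cls)
            assert {round(1 - f, 12) for f in fr} == {round(f, 12) for f in fr}

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            canonical_fraction_sets("mipz", 2)


class TestModelComparison:
    @staticmethod
    def _mirrored(s_values, lengths):
        rows = []
        for s, L in zip(s_values, lengths):
            rows.append(("x", L, s, 0.5))
            rows.append(("x", L, 1 - s, 0.5))
        return pd.DataFrame(rows, columns=["cell_id", "L_mother", "s", "weight"])

    def test_third_fraction_data_prefers_odd_model(self):
        rng = np.random.default_rng(1)
        s = np.clip(rng.normal(1 / 3, 0.02, 100), 0.02, 0.49)
        m = self._mirrored(s, np.full(100, 6.0))
        out = compare_division_models(m)
        assert out["winner"] == "odd_fraction"

    def test_midcell_only_data_is_a_tie(self):
        # both models place a single site at 1/2 for short cells
        s = np.full(50, 0.5)
        m = pd.DataFrame({"cell_id": "x", "L_mother": 2.0, "s": s, "weight": 1.0})
        out = compare_division_models(m)
        assert out["winner"] == "tie"

    def test_min_fraction_data_prefers_min_model(self):
        rng = np.random.default_rng(2)
        s = np.clip(rng.normal(1 / 6, 0.02, 100), 0.02, 0.49)
        m = self._mirrored(s, np.full(100, 9.0))  # long cells: m=3 sites
        out = compare_division_models(m)
        assert out["winner"] == "min_system"

    def test_degenerate_noise_rejected(self):
        m = pd.DataFrame({"cell_id": "x", "L_mother": 2.0, "s": [0.5],
                          "weight": [1.0]})
        with pytest.raises(ValidationError):
            compare_division_models(m, noise_sd_S=0.0)

    def test_winner_stable_as_mixture_sd_grows(self):
        rng = np.random.default_rng(4)
        s = np.clip(rng.normal(1 / 3, 0.01, 80), 0.02, 0.49)
        m = self._mirrored(s, np.full(80, 6.0))
        winners = [compare_division_models(m, noise_sd_S=sd)["winner"]
                   for sd in (0.01, 0.02, 0.05, 0.1)]
        assert set(winners) == {"odd_fraction"}


class TestModelResultsWorkflow:
    def test_fit_produces_consistent_results(self, reference_measurements):
        _, meas = reference_measurements
        res = DivisionSiteModel(meas).fit()
        assert res.n_cells == 300
        assert res.model_comparison["winner"] == "odd_fraction"
        assert "odd_fraction" in res.summary()
        frame = res.records_frame()
        assert set(frame["fraction_class"]) == {"1/2", "1/3", "1/4"}

    def test_from_dataframe_roundtrip(self, reference_measurements):
        _, meas = reference_measurements
        df = pd.DataFrame({
            "cell_id": [m.cell_id for m in meas],
            "replicate": [m.replicate for m in meas],
            "d1_um": [m.d1 for m in meas],
            "d2_um": [m.d2 for m in meas],
        })
        res = DivisionSiteModel.from_dataframe(df).fit()
        assert res.n_cells == len(meas)

    def test_empty_measurements_rejected(self):
        with pytest.raises(ValidationError):
            DivisionSiteModel([])
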