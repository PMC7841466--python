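"""Parameter calibration chain against published values and round-trips."""

import math

import pytest

import delayrisk as dr


def sigfig(x, n=3):
    if x == 0:
        return 0.0
    return float(f"%.{n - 1}e" % x)


class TestGeometry:
    @pytest.mark.parametrize(
        "diameter, expected",
        [(0.5, 6.54e6), (3.0, 1.41e9), (5.0, 6.54e9)],
    )
    def test_published_cell_counts(self, diameter, expected):
        p0 = dr.cells_from_diameter(dr.TumorGeometry(diameter))
        assert sigfig(p0) == expected

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            dr.TumorGeometry(-1.0)
        with pytest.raises(ValueError):
            dr.TumorGeometry(1.0, cell_density_per_cm3=0.0)


class TestSurvivingFraction:
    @pytest.mark.parametrize(
        "p0, expected",
        [(1.413716694e9, 7.45e-11), (6.544984695e6, 1.61e-8), (6.544984695e9, 1.61e-11)],
    )
    def test_published_values(self, p0, expected):
        assert sigfig(dr.surviving_fraction_from_baseline(0.9, p0)) == expected

    def test_unit_product(self):
        assert dr.surviving_fraction_from_baseline(math.exp(-1.0), 1.0) == pytest.approx(1.0)

    def test_roundtrip_through_tcp(self):
        p0 = 3.7e8
        s = dr.surviving_fraction_from_baseline(0.77, p0)
        params = dr.TumorParameters(p0=p0, s=s, g_mean=0.1, g_sd=0.0, k=0.0)
        assert dr.tumor_control_probability(params, 0.1, 0.0) == pytest.approx(
            0.77, abs=1e-14
        )

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            dr.surviving_fraction_from_baseline(1.2, 1e9)
        with pytest.raises(ValueError):
            dr.surviving_fraction_from_baseline(0.9, -5.0)


class TestGrowthRates:
    @pytest.mark.parametrize(
        "days, expected, decimals",
        [(99.0, 0.210, 3), (211.0, 0.099, 3), (348.0, 0.0598, 4)],
    )
    def test_published_means(self, days, expected, decimals):
        # compared at the precision each value is printed with
        assert round(dr.growth_rate_from_doubling_time(days), decimals) == expected

    def test_one_month_doubling(self):
        assert dr.growth_rate_from_doubling_time(30.0) == pytest.approx(math.log(2.0))

    @pytest.mark.parametrize(
        "summary, expected",
        [
            (dr.DoublingTimeSummary(99, 61, 112, "full_range"), 0.0282),
            (dr.DoublingTimeSummary(211, 112, 404, "full_range"), 0.032),
            (dr.DoublingTimeSummary(348, 222, 492, "interquartile"), 0.0361),
        ],
    )
    def test_published_sds(self, summary, expected):
        assert sigfig(dr.growth_sd_from_spread(summary)) == expected

    def test_symmetric_spread_is_identity(self):
        # when both one-sided estimates equal s, the geometric mean is s
        g_med = dr.growth_rate_from_doubling_time(100.0)
        s = 0.01
        z = 2.0
        lower = math.log(2.0) * dr.DAYS_PER_MONTH / (g_med + z * s)
        upper = math.log(2.0) * dr.DAYS_PER_MONTH / (g_med - z * s)
        summary = dr.DoublingTimeSummary(100.0, lower, upper, "full_range")
        assert dr.growth_sd_from_spread(summary) == pytest.approx(s, rel=1e-12)

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            dr.DoublingTimeSummary(100, 120, 90, "full_range")
        with pytest.raises(ValueError):
            dr.growth_rate_from_doubling_time(0.0)


class TestMetastasisRate:
    @pytest.mark.parametrize(
        "label, printed_k",
        [("head_and_neck", 1.51e-12), ("colorectal", 1.95e-12), ("lung", 1.40e-10)],
    )
    def test_published_k_within_three_percent(self, label, printed_k):
        inp = dr.LITERATURE_INPUTS[label]
        params = dr.build_parameter_set(
            inp["geometry"], inp["baseline"], inp["doubling"], inp["metastasis"],
            label=label, k_mode="point",
        )
        assert params.k == pytest.approx(printed_k, rel=0.03)

    @pytest.mark.parametrize("label", ["head_and_neck", "colorectal", "lung"])
    def test_distributional_k_below_point_k(self, label):
        # Jensen: averaging the (convex-in-g) metastasis probability raises
        # E[PM] above PM(G), so matching the same observation needs smaller k
        inp = dr.LITERATURE_INPUTS[label]
        args = (inp["geometry"], inp["baseline"], inp["doubling"], inp["metastasis"])
        point = dr.build_parameter_set(*args, label=label, k_mode="point")
        dist = dr.build_parameter_set(*args, label=label, k_mode="distributional")
        assert dist.k < point.k
        assert dist.k == pytest.approx(point.k, rel=0.05)

    def test_point_mode_roundtrip(self):
        obs = dr.MetastasisObservation(0.60, 14.9)
        k = dr.calibrate_metastasis_rate(obs, p0=1.41e9, g_mean=0.210)
        params = dr.TumorParameters(p0=1.41e9, s=1e-10, g_mean=0.210, g_sd=0.0, k=k)
        pm = dr.metastasis_probability(params, 0.210, 14.9)
        assert pm == pytest.approx(0.60, rel=1e-12)

    def test_distributional_mode_roundtrip(self):
        obs = dr.MetastasisObservation(0.17, 5.0)
        k = dr.calibrate_metastasis_rate(
            obs, p0=6.54e9, g_mean=0.099, mode="distributional", g_sd=0.032
        )
        params = dr.TumorParameters(p0=6.54e9, s=1e-10, g_mean=0.099, g_sd=0.032, k=k)
        mean_pm = dr.expect_over_growth(params, 5.0, dr.metastasis_probability)
        assert mean_pm == pytest.approx(0.17, rel=1e-10)

    def test_zero_probability_gives_zero_rate(self):
        obs = dr.MetastasisObservation(0.0, 5.0)
        assert dr.calibrate_metastasis_rate(obs, 1e9, 0.1) == 0.0

    def test_invalid_observation_rejected(self):
        with pytest.raises(ValueError):
            dr.MetastasisObservation(1.0, 5.0)
        with pytest.raises(ValueError):
            dr.MetastasisObservation(0.5, 0.0)


class TestBuildParameterSet:
    def test_full_chain_head_and_neck(self):
        inp = dr.LITERATURE_INPUTS["head_and_neck"]
        p = dr.build_parameter_set(
            inp["geometry"], inp["baseline"], inp["doubling"], inp["metastasis"],
            label="head_and_neck",
        )
        assert sigfig(p.p0) == 1.41e9
        assert sigfig(p.s) == 7.45e-11
        assert sigfig(p.g_mean) == 0.210
        assert sigfig(p.g_sd) == 0.0282
        assert p.k == pytest.approx(1.51e-12, rel=0.03)
        assert p.m0 == 0.0

    def test_deterministic(self):
        inp = dr.LITERATURE_INPUTS["lung"]
        args = (inp["geometry"], inp["baseline"], inp["doubling"], inp["metastasis"])
        assert dr.build_parameter_set(*args) == dr.build_parameter_set(*args)

    def test_baseline_tcp_property(self):
        p = dr.published_parameters("colorectal", "derived")
        assert p.baseline_tcp == pytest.approx(0.9, abs=1e-14)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        inp = dr.LITERATURE_INPUTS["lung"]
        derived = dr.published_parameters("lung", "derived")
        path = tmp_path / "lung.yaml"
        dr.write_parameter_config(
            path, "lung", inp["geometry"], inp["baseline"], inp["doubling"],
            inp["metastasis"], derived=derived,
        )
        back = dr.read_parameter_config(path)
        assert back["label"] == "lung"
        assert back["geometry"] == inp["geometry"]
        assert back["doubling"] == inp["doubling"]
        assert back["metastasis"] == inp["metastasis"]
        rebuilt = dr.build_parameter_set(
            back["geometry"], back["baseline"], back["doubling"], back["metastasis"],
            label=back["label"],
        )
        assert rebuilt.k == pytest.approx(derived.k, rel=1e-12)

    def test_missing_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cancer_label: x\ndiameter_cm: 1.0\n")
        with pytest.raises(ValueError, match="missing keys"):
            dr.read_parameter_config(path)

    def test_invalid_values_rejected(self, tmp_path):
        inp = dr.LITERATURE_INPUTS["lung"]
        path = tmp_path / "neg.yaml"
        dr.write_parameter_config(
            path, "x", inp["geometry"], inp["baseline"], inp["doubling"], inp["metastasis"]
        )
        text = path.read_text().replace("diameter_cm: 0.5", "diameter_cm: -0.5")
        path.write_text(text)
        with pytest.raises(ValueError):
            dr.read_parameter_config(path)
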