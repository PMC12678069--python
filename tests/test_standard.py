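"""Centile standard: validation, interpolation, extension, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from newborntypes import GrowthStandard, load_standard
from newborntypes.standard import OutOfRangeError, StandardError


def two_knot_standard(entries):
    frames = []
    for sex in ("male", "female"):
        frames.append(
            pd.DataFrame(
                [{"sex": sex, "ga_days": d, "p10_g": p10, "p90_g": p90} for d, p10, p90 in entries]
            )
        )
    return GrowthStandard(pd.concat(frames, ignore_index=True))


class TestValidation:
    def test_crossing_centiles_rejected(self):
        with pytest.raises(StandardError, match="crossing"):
            two_knot_standard([(280, 4000, 4000), (287, 2900, 4100)])

    def test_duplicate_knots_rejected(self):
        with pytest.raises(StandardError, match="duplicate"):
            two_knot_standard([(280, 2900, 4000), (280, 2950, 4050)])

    def test_single_sex_rejected(self):
        df = pd.DataFrame(
            [{"sex": "male", "ga_days": 280, "p10_g": 2900, "p90_g": 4000}]
        )
        with pytest.raises(StandardError, match="female"):
            GrowthStandard(df)

    def test_gap_warns_but_loads(self):
        with pytest.warns(UserWarning, match="gaps"):
            two_knot_standard([(280, 2900, 4000), (300, 3000, 4100)])


class TestLoadStandard:
    def test_week_indexed_file_converted_to_days(self, tmp_path):
        rows = ["sex,ga_weeks,p10_g,p90_g"]
        for sex in ("male", "female"):
            for w in (38, 39, 40):
                rows.append(f"{sex},{w},{2800 + 10 * w},{3900 + 10 * w}")
        path = tmp_path / "std.csv"
        path.write_text("\n".join(rows) + "\n")
        std = load_standard(path)
        assert std.native_range("male") == (266, 280)
        assert std.centile_limits("male", 266) == (3180, 4280)

    def test_invalid_file_raises_with_context(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sex,ga_days,p10_g,p90_g\nmale,280,4000,4000\nfemale,280,2900,4000\n"
        )
        with pytest.raises(StandardError):
            load_standard(path)


class TestCentileLimits:
    STD = None

    @classmethod
    def setup_class(cls):
        cls.STD = two_knot_standard([(273, 2850, 3950), (280, 2900, 4000)])

    def test_knot_identity(self):
        assert self.STD.centile_limits("male", 280) == (2900, 4000)

    def test_linear_interpolation_between_knots(self):
        p10, p90 = self.STD.centile_limits("female", 277)
        assert p10 == pytest.approx(2850 + (4 / 7) * 50)
        assert p90 == pytest.approx(3950 + (4 / 7) * 50)

    def test_out_of_range_raises(self):
        with pytest.raises(OutOfRangeError):
            self.STD.centile_limits("male", 154)

    def test_week_floor_mode(self):
        std = GrowthStandard(
            self.STD.to_frame(), day_interpolation=False
        )
        # 278 days floors to completed week 39 = 273 days
        assert std.centile_limits("male", 278) == (2850, 3950)


def test_toy_gaussian_standard_matches_normal_quantiles(flat_standard):
    """p10/p90 of a N(3000, 400) family are the 10%/90% normal quantiles."""
    p10, p90 = flat_standard.centile_limits("female", 280)
    assert p10 == pytest.approx(stats.norm.ppf(0.10, 3000, 400), abs=1e-6)
    assert p90 == pytest.approx(stats.norm.ppf(0.90, 3000, 400), abs=1e-6)
    assert p10 == pytest.approx(2487.4, abs=0.1)
    assert p90 == pytest.approx(3512.6, abs=0.1)


class TestExtension:
    def test_clamp_holds_boundary_values(self):
        std = two_knot_standard([(168, 600, 900), (175, 700, 1000), (280, 2900, 4000)])
        ext = std.extend(154, 280, method="clamp")
        assert ext.centile_limits("male", 154) == std.centile_limits("male", 168)

    def test_linear_extrapolation_continues_outer_slope(self):
        std = two_knot_standard([(294, 3000, 4100), (301, 3010, 4110)])
        ext = std.extend(294, 308, method="linear_extrapolate")
        assert ext.centile_limits("female", 308) == (3020, 4120)
        assert "extended" in ext.provenance

    def test_extrapolation_to_nonpositive_weight_is_error(self):
        std = two_knot_standard([(280, 2900, 4000), (287, 400, 4100)])
        with pytest.raises(StandardError):
            std.extend(280, 350, method="linear_extrapolate")

    def test_target_must_contain_native_range(self):
        std = two_knot_standard([(273, 2850, 3950), (280, 2900, 4000)])
        with pytest.raises(ValueError):
            std.extend(275, 280)


class TestClassify:
    def test_boundaries_inclusive_to_aga(self, flat_standard):
        p10, p90 = flat_standard.centile_limits("female", 280)
        bw = np.array([p10 - 1, p10, p90, p90 + 1])
        out = flat_standard.classify(bw, "female", np.full(4, 280))
        assert list(out) == ["SGA", "AGA", "AGA", "LGA"]

    def test_exactly_one_class_per_record(self, toy_standard):
        rng = np.random.default_rng(3)
        ga = rng.integers(154, 315, 500)
        sex = np.where(rng.random(500) < 0.5, "male", "female")
        bw = rng.integers(300, 6000, 500)
        out = toy_standard.classify(bw, sex, ga)
        assert set(out) <= {"SGA", "AGA", "LGA"}
        assert len(out) == 500

    def test_monotone_in_birthweight(self, toy_standard):
        """Increasing weight never moves class toward SGA."""
        order = {"SGA": 0, "AGA": 1, "LGA": 2}
        weights = np.arange(300, 6000, 50)
        for sex in ("male", "female"):
            for ga in (154, 200, 259, 280, 314):
                classes = toy_standard.classify(
                    weights, np.repeat(sex, weights.size), np.full(weights.size, ga)
                )
                ranks = [order[c] for c in classes]
                assert ranks == sorted(ranks)
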