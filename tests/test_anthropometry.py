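import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg import sim
from autozyg.anthropometry import (
    HAND_BONES,
    NormTable,
    ZProfile,
    compare_profiles,
    lookup_norm,
    profile_hands,
    profiles_frame,
    z_score,
)
from autozyg.pedigree import FEMALE, MALE


class TestZScore:
    def test_at_the_mean(self):
        assert z_score(40.0, 40.0, 2.0) == 0.0

    def test_marked_shortening_examples(self):
        """Seven SD and 5.3 SD below the reference mean."""
        assert z_score(26.0, 40.0, 2.0) == pytest.approx(-7.0)
        assert z_score(29.4, 40.0, 2.0) == pytest.approx(-5.3)

    def test_requires_positive_sd(self):
        with pytest.raises(ValueError):
            z_score(40.0, 40.0, 0.0)


def tiny_norms():
    rows = []
    for age, mean, sd in [(20.0, 40.0, 2.0), (40.0, 44.0, 4.0)]:
        rows.append(
            {
                "bone_id": "MC1",
                "sex": MALE,
                "age_years": age,
                "mean_mm": mean,
                "sd_mm": sd,
            }
        )
    return NormTable(pd.DataFrame(rows))


class TestLookupNorm:
    def test_exact_tabulated_age(self):
        assert lookup_norm(tiny_norms(), "MC1", MALE, 20.0) == (40.0, 2.0)
        assert lookup_norm(tiny_norms(), "MC1", MALE, 40.0) == (44.0, 4.0)

    def test_midway_linear_interpolation(self):
        mean, sd = lookup_norm(tiny_norms(), "MC1", MALE, 30.0)
        assert mean == pytest.approx(42.0)
        assert sd == pytest.approx(3.0)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="outside tabulated range"):
            lookup_norm(tiny_norms(), "MC1", MALE, 19.0)
        with pytest.raises(ValueError, match="outside tabulated range"):
            lookup_norm(tiny_norms(), "MC1", MALE, 41.0)

    def test_unknown_bone_or_sex(self):
        with pytest.raises(KeyError):
            lookup_norm(tiny_norms(), "PP1", MALE, 25.0)
        with pytest.raises(KeyError):
            lookup_norm(tiny_norms(), "MC1", FEMALE, 25.0)


class TestNormTable:
    def test_rejects_nonpositive_sd(self):
        frame = tiny_norms().frame.copy()
        frame.loc[0, "sd_mm"] = 0.0
        with pytest.raises(ValueError, match="SD"):
            NormTable(frame)

    def test_rejects_duplicate_ages(self):
        frame = tiny_norms().frame.copy()
        frame.loc[1, "age_years"] = 20.0
        with pytest.raises(ValueError, match="increasing"):
            NormTable(frame)

    def test_tsv_round_trip(self, tmp_path):
        norms = sim.default_norm_table()
        path = tmp_path / "norms.tsv"
        norms.write_tsv(path)
        back = NormTable.read_tsv(path)
        pd.testing.assert_frame_equal(back.frame, norms.frame)


class TestProfileHands:
    def test_constant_offset_profile(self):
        """Lengths planted exactly 2 SD below the mean give z = −2 for
        every one of the 19 bones."""
        norms = sim.default_norm_table()
        rows = []
        for bone in HAND_BONES:
            mean, sd = lookup_norm(norms, bone, FEMALE, 33.0)
            rows.append(
                {
                    "individual": "P",
                    "side": "left",
                    "bone_id": bone,
                    "length_mm": mean - 2.0 * sd,
                }
            )
        persons = pd.DataFrame(
            {"individual": ["P"], "sex": [FEMALE], "age_years": [33.0]}
        )
        profiles = profile_hands(pd.DataFrame(rows), norms, persons)
        assert len(profiles) == 1
        assert set(profiles[0].z) == set(HAND_BONES)
        assert all(z == pytest.approx(-2.0) for z in profiles[0].z.values())
        frame = profiles_frame(profiles)
        assert len(frame) == 19

    def test_missing_person_raises(self):
        norms = sim.default_norm_table()
        meas = pd.DataFrame(
            [{"individual": "X", "side": "left", "bone_id": "MC1", "length_mm": 40.0}]
        )
        persons = pd.DataFrame(
            {"individual": ["Y"], "sex": [MALE], "age_years": [30.0]}
        )
        with pytest.raises(KeyError, match="X"):
            profile_hands(meas, norms, persons)


def _profile(iid, side, value, bones=HAND_BONES):
    return ZProfile(iid, side, {b: float(value) for b in bones})


class TestCompareProfiles:
    def test_group_difference_and_flag(self):
        """Affected hands sitting in [−3, −1] vs unaffected in [−1, 1]
        produce a ≤ −1 SD group difference and a brachydactyly call."""
        affected = [_profile("A", "left", -2.0), _profile("A", "right", -2.0)]
        unaffected = [_profile("U", "left", 0.0)]
        cmp = compare_profiles(affected, unaffected)
        assert cmp.mean_z_affected == pytest.approx(-2.0)
        assert cmp.mean_z_unaffected == pytest.approx(0.0)
        assert cmp.difference == pytest.approx(-2.0)
        assert cmp.brachydactyly
        assert cmp.marked_bones == []

    def test_small_deficit_not_called(self):
        cmp = compare_profiles(
            [_profile("A", "left", -0.5)], [_profile("U", "left", 0.0)]
        )
        assert not cmp.brachydactyly

    def test_marked_bones_detected_at_threshold(self):
        prof = _profile("A", "left", -2.0)
        prof.z["MC1"] = -7.0
        prof.z["PP1"] = -5.0  # threshold is inclusive (z <= -5)
        cmp = compare_profiles([prof], [_profile("U", "right", 0.0)])
        marked = {(b, z) for _, _, b, z in cmp.marked_bones}
        assert marked == {("MC1", -7.0), ("PP1", -5.0)}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles([], [_profile("U", "left", 0.0)])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        shift=st.floats(-3, 3, allow_nan=False),
        base=st.floats(-2, 2, allow_nan=False),
    )
    def test_difference_is_shift_equivariant(self, shift, base):
        """Adding a constant to every affected z moves the group difference
        by exactly that constant."""
        affected = [_profile("A", "left", base)]
        unaffected = [_profile("U", "left", 0.25)]
        d0 = compare_profiles(affected, unaffected).difference
        shifted = [_profile("A", "left", base + shift)]
        d1 = compare_profiles(shifted, unaffected).difference
        assert d1 == pytest.approx(d0 + shift, abs=1e-9)


def test_plot_profiles_writes_png(tmp_path):
    from autozyg.anthropometry import plot_profiles

    path = tmp_path / "profiles.png"
    plot_profiles([_profile("A", "left", -2.0)], path, title="demo")
    assert path.stat().st_size > 0
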