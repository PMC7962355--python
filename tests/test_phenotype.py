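"""Phenotype-microarray thresholding and growth calling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmforge.phenotype import (
    DYE_WAVELENGTH,
    PlateError,
    PmPlate,
    WellReading,
    call_growth,
    od_increase,
    plate_threshold,
    read_plates_csv,
    replicate_thresholds,
    write_plates_csv,
)
from gsmforge.synth import make_pm_fixture


def _plate(deltas, replicate=1, plate_id="P", substrates=None):
    wells = {}
    for i, d in enumerate(deltas):
        sub = substrates[i] if substrates else f"S{i:03d}"
        wells[f"W{i:03d}"] = {
            DYE_WAVELENGTH: WellReading(sub, 0.1, 0.1 + d),
        }
    return PmPlate(plate_id=plate_id, replicate=replicate, wells=wells)


class TestThreshold:
    def test_single_outlier_example(self):
        """Bulk of zeros plus one spike: the spike is truncated away,
        the retained moments are 0/0, so the cutoff sits at exactly 0."""
        t = plate_threshold([0, 0, 0, 0, 1])
        assert t.truncation_mean == pytest.approx(0.2)
        assert t.n_retained == 4
        assert t.mean == pytest.approx(0.0)
        assert t.sd == pytest.approx(0.0)
        assert t.cutoff == pytest.approx(0.0)

    def test_all_identical_values(self):
        t = plate_threshold([0.05] * 10)
        assert t.n_retained == 10
        assert t.cutoff == pytest.approx(0.05)

    def test_textbook_moments(self):
        # values {1,2,3,4,100}: mean 22, retained {1,2,3,4},
        # retained mean 2.5, n-1 sd = sqrt(5/3)
        t = plate_threshold([1, 2, 3, 4, 100])
        assert t.mean == pytest.approx(2.5)
        assert t.sd == pytest.approx((5 / 3) ** 0.5)
        assert t.cutoff == pytest.approx(2.5 + (5 / 3) ** 0.5)

    def test_too_few_values(self):
        with pytest.raises(PlateError):
            plate_threshold([0.1])

    def test_degenerate_distribution(self):
        # only one value at or below the mean
        with pytest.raises(PlateError, match="degenerate"):
            plate_threshold([0.0, 10.0, 10.0, 10.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=4,
            max_size=40,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, values, rnd):
        try:
            base = plate_threshold(values)
        except PlateError:
            return
        shuffled = list(values)
        rnd.shuffle(shuffled)
        other = plate_threshold(shuffled)
        assert other.cutoff == pytest.approx(base.cutoff, abs=1e-12)
        assert other.n_retained == base.n_retained

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=4,
            max_size=40,
        ),
        st.floats(min_value=-0.5, max_value=0.5, allow_nan=False),
    )
    def test_location_equivariance(self, values, shift):
        """Shifting every ΔOD by c shifts the cutoff by exactly c."""
        try:
            base = plate_threshold(values)
        except PlateError:
            return
        shifted = plate_threshold([v + shift for v in values])
        assert shifted.cutoff == pytest.approx(base.cutoff + shift, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-9)


class TestCallGrowth:
    def test_majority_rule_boundary(self):
        """1 positive of 2 replicates reaches the ≥50% rule; 1 of 3 does
        not."""
        bulk = [0.0] * 9
        hot = bulk[:-1] + [1.0]
        two = [_plate(hot, 1), _plate(bulk, 2)]
        assert call_growth(two).calls["S008"] is True
        three = [_plate(hot, 1), _plate(bulk, 2), _plate(bulk, 3)]
        assert call_growth(three).calls["S008"] is False

    def test_values_record_replicate_fraction(self):
        bulk = [0.0] * 9
        hot = bulk[:-1] + [1.0]
        out = call_growth([_plate(hot, 1), _plate(bulk, 2)])
        assert out.values["S008"] == pytest.approx(0.5)
        assert out.provenance == "measured"

    def test_exclusion_removes_substrate_entirely(self):
        bulk = [0.01] * 8 + [1.0]
        plates = [_plate(bulk, r) for r in (1, 2)]
        out = call_growth(plates, exclude={"S008"})
        assert "S008" not in out.calls

    def test_layout_mismatch_raises(self):
        a = _plate([0.01] * 5, 1)
        b = _plate([0.01] * 5, 2, substrates=["X"] * 5)
        with pytest.raises(PlateError, match="layout"):
            call_growth([a, b])

    def test_no_plates_raises(self):
        with pytest.raises(PlateError):
            call_growth([])

    def test_missing_wavelength_raises(self):
        plate = _plate([0.01] * 5, 1)
        del plate.wells["W000"][DYE_WAVELENGTH]
        with pytest.raises(PlateError, match="490"):
            od_increase(plate)


class TestPlantedRecovery:
    def test_all_planted_positives_called(self):
        plates, truth = make_pm_fixture(seed=0)
        out = call_growth(plates)
        called = {s for s, v in out.calls.items() if v}
        assert truth.metabolized_substrates <= called

    @pytest.mark.parametrize("seed", range(5))
    def test_sensitivity_is_one_across_seeds(self, seed):
        plates, truth = make_pm_fixture(seed=seed)
        out = call_growth(plates)
        assert all(out.calls[s] for s in truth.metabolized_substrates)

    def test_sensitivity_monotone_in_effect_size(self):
        """Mean sensitivity over seeds is non-decreasing as the planted
        effect grows from marginal to unmistakable."""
        sens = []
        for effect in (1.0, 3.0, 10.0):
            hits = total = 0
            for seed in range(8):
                plates, truth = make_pm_fixture(effect_sizes=effect, seed=seed)
                out = call_growth(plates)
                hits += sum(out.calls[s] for s in truth.metabolized_substrates)
                total += len(truth.metabolized_substrates)
            sens.append(hits / total)
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] == 1.0

    def test_replicate_thresholds_one_per_plate(self):
        plates, _ = make_pm_fixture(seed=1)
        ths = replicate_thresholds(plates)
        assert len(ths) == len(plates)
        for t in ths.values():
            assert t.sd >= 0 and t.n_retained >= 2


class TestPlateIo:
    def test_csv_roundtrip(self, tmp_path):
        plates, _ = make_pm_fixture(n_wells=24, planted_positives=4, seed=2)
        path = tmp_path / "plates.csv"
        write_plates_csv(plates, str(path))
        back = read_plates_csv(str(path))
        assert len(back) == len(plates)
        # calls survive the (rounded) round trip
        assert call_growth(back).calls == call_growth(plates).calls

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plate_id,replicate\nP,1\n")
        with pytest.raises(PlateError, match="columns"):
            read_plates_csv(str(path))

    def test_same_seed_same_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_plates_csv(make_pm_fixture(seed=4)[0], str(p1))
        write_plates_csv(make_pm_fixture(seed=4)[0], str(p2))
        assert p1.read_bytes() == p2.read_bytes()
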