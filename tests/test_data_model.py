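import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ees_profile.data_model import (
    ChromatogramRecord,
    DescriptorMatrix,
    MobilePhaseGrid,
    SchemaError,
    ScalerParams,
    SplitValidationError,
    SubsetSplit,
    autoscale,
    descale,
    read_matrix,
    validate_split,
    write_chromatograms,
    write_descriptors,
    write_target,
)


class TestMobilePhaseGrid:
    def test_default_acn_mapping(self):
        grid = MobilePhaseGrid()
        assert grid.acn_percent == (30, 40, 50, 60, 70, 80, 90, 95, 98)
        assert grid.indices == tuple(range(1, 10))
        assert grid.acn_fraction(1) == 0.30
        assert grid.acn_fraction(9) == 0.98

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            MobilePhaseGrid(acn_percent=(30, 40, 40, 60, 70, 80, 90, 95, 98))


class TestChromatogramRecord:
    def test_donepezil_style_record(self):
        rec = ChromatogramRecord("C1", 2, 3.1, 51.2)
        assert (rec.rs, rec.k2, rec.k1) == (3.1, 51.2, None)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mp_index=0, rs=1.0, k2=1.0),
            dict(mp_index=1, rs=-0.1, k2=1.0),
            dict(mp_index=1, rs=1.0, k2=-1.0),
            dict(mp_index=1, rs=1.0, k2=1.0, k1=2.0),  # k1 > k2
        ],
    )
    def test_invariant_violations(self, kwargs):
        with pytest.raises(ValueError):
            ChromatogramRecord("C1", **kwargs)


class TestAutoscale:
    def test_hand_zscore(self):
        scaled, params = autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(scaled.ravel(), [-1, 0, 1])
        assert params.center[0] == 2.0 and params.scale[0] == 1.0

    def test_constant_column_maps_to_zeros(self):
        scaled, params = autoscale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(scaled[:, 0] == 0.0)
        assert params.scale[0] == 0.0 and params.center[0] == 5.0

    def test_descale_restores_constant(self):
        out = descale(np.zeros((3, 1)), ScalerParams([5.0], [0.0]))
        assert np.all(out == 5.0)

    @settings(deadline=None, max_examples=30)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(3, 12), st.integers(1, 6)),
            elements=st.floats(-1e4, 1e4, allow_nan=False),
        )
    )
    def test_round_trip_identity(self, m):
        scaled, params = autoscale(m)
        assert np.allclose(descale(scaled, params), m, atol=1e-10)
        nonconst = params.scale > 0
        if nonconst.any():
            assert np.all(np.abs(scaled[:, nonconst].mean(axis=0)) < 1e-9)
            assert np.all(np.abs(scaled[:, nonconst].std(axis=0, ddof=1) - 1) < 1e-9)

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            autoscale(np.ones((1, 3)))


class TestValidateSplit:
    def test_reference_geometry_valid(self):
        split = SubsetSplit(tuple(range(10, 76)), tuple(range(7)), tuple(range(7, 10)))
        assert validate_split(split, 76) is split

    def test_overlap_rejected(self):
        split = SubsetSplit(tuple(range(10, 76)), tuple(range(7)), (6, 8, 9))
        with pytest.raises(SplitValidationError, match="overlap"):
            validate_split(split, 76)

    def test_wrong_va_size_rejected(self):
        split = SubsetSplit(tuple(range(9, 76)), tuple(range(6)), (6, 7, 8))
        with pytest.raises(SplitValidationError, match="validation"):
            validate_split(split, 76)

    def test_out_of_range_rejected(self):
        split = SubsetSplit(tuple(range(10, 76)), (0, 1, 2, 3, 4, 5, 76), (7, 8, 9))
        with pytest.raises(SplitValidationError, match="out-of-range"):
            validate_split(split, 77 - 1)


class TestCSVRoundTrips:
    def test_descriptor_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "x.csv"
        write_descriptors(small_dataset.descriptors, path)
        back = read_matrix(path, "descriptor")
        assert back.compound_ids == small_dataset.descriptors.compound_ids
        assert back.columns == small_dataset.descriptors.columns
        assert np.array_equal(back.values, small_dataset.descriptors.values)

    def test_target_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "t.csv"
        write_target(small_dataset.target, path)
        back = read_matrix(path, "target")
        assert np.array_equal(back.values, small_dataset.target.values)

    def test_chromatogram_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "c.csv"
        write_chromatograms(list(small_dataset.chromatograms), path)
        back = read_matrix(path, "chromatogram")
        assert back == list(small_dataset.chromatograms)

    def test_chromatogram_row_parsing(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("compound_id,mp_index,rs,k2\nC1,2,3.1,51.2\n")
        (rec,) = read_matrix(path, "chromatogram")
        assert rec == ChromatogramRecord("C1", 2, 3.1, 51.2)

    def test_duplicate_compound_id_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("compound_id,x1\nC1,1.0\nC1,2.0\n")
        with pytest.raises(SchemaError, match="C1"):
            read_matrix(path, "descriptor")

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("compound_id,x1,x2\nC1,1.0,oops\n")
        with pytest.raises(SchemaError, match="x2"):
            read_matrix(path, "descriptor")

    def test_shape_contract(self, tmp_path):
        header = "compound_id," + ",".join(f"x{i}" for i in range(1, 63))
        rows = [f"C{r}," + ",".join("0.5" for _ in range(62)) for r in range(3)]
        path = tmp_path / "x.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        m = read_matrix(path, "descriptor")
        assert (m.n_compounds, m.n_descriptors) == (3, 62)


class TestDescriptorMatrix:
    def test_select_preserves_order(self, small_dataset):
        sub = small_dataset.descriptors.select(["S003", "S001"])
        assert sub.compound_ids == ("S003", "S001")
        assert np.array_equal(sub.values[0], small_dataset.descriptors.values[2])

    def test_nan_rejected(self):
        with pytest.raises(SchemaError, match="non-finite"):
            DescriptorMatrix(("a", "b"), ("x1",), np.array([[1.0], [np.nan]]))
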