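"""Experiment I/O, plate maps and feature export."""

import numpy as np
import pandas as pd
import pytest

from calimetry.errors import ConfigError, FormatError, LayoutError
from calimetry.plate import (
    UNASSIGNED,
    Condition,
    FovRecording,
    PlateMap,
    apply_plate_map,
    export_feature_tables,
    load_experiment,
    write_experiment,
)


def _recordings(n_wells=2, fovs=3, T=10, side=8):
    rng = np.random.default_rng(0)
    recs = []
    for w in range(n_wells):
        well = f"B{w + 1:02d}"
        for f in range(fovs):
            recs.append(
                FovRecording(
                    well_id=well,
                    fov_index=f,
                    frame_rate_hz=10.0,
                    video=rng.random((T, side, side)).astype(np.float32),
                    label_mask=rng.integers(0, 3, (side, side)).astype(np.uint16),
                )
            )
    return recs


class TestLoadExperiment:
    @pytest.mark.parametrize("dialect", ["tiff", "zarr"])
    def test_round_trip_bit_for_bit(self, tmp_path, dialect):
        recs = _recordings()
        write_experiment(tmp_path, recs, dialect=dialect)
        loaded = load_experiment(tmp_path)
        assert len(loaded) == 6
        for orig, back in zip(recs, loaded):
            assert (orig.well_id, orig.fov_index) == (back.well_id, back.fov_index)
            np.testing.assert_array_equal(orig.get_video(), back.get_video())
            np.testing.assert_array_equal(orig.label_mask, back.label_mask)
            assert back.n_frames == 10

    def test_mask_video_shape_mismatch(self, tmp_path):
        import tifffile

        rec = _recordings(1, 1)[0]
        write_experiment(tmp_path, [rec])
        tifffile.imwrite(tmp_path / "B01" / "fov000_mask.tif",
                         np.zeros((16, 16), dtype=np.uint16))
        loaded = load_experiment(tmp_path)
        with pytest.raises(FormatError, match="B01"):
            loaded[0].get_video()

    def test_unknown_well_label(self, tmp_path):
        write_experiment(tmp_path, _recordings(1, 1))
        (tmp_path / "notawell").mkdir()
        with pytest.raises(LayoutError):
            load_experiment(tmp_path)

    def test_missing_frame_rate(self, tmp_path):
        (tmp_path / "experiment.yaml").write_text("format: tiff\n")
        with pytest.raises(ConfigError):
            load_experiment(tmp_path)

    def test_invalid_well_name_rejected(self):
        with pytest.raises(LayoutError):
            FovRecording(well_id="Z99", fov_index=0, frame_rate_hz=10.0,
                         video=np.zeros((1, 2, 2)))


class TestPlateMap:
    def test_yaml_round_trip_and_grouping(self, tmp_path):
        (tmp_path / "map.yaml").write_text(
            "wells:\n"
            "  B01: {genotype: control}\n"
            "  B02: {genotype: mutant, treatment: drug, dose: 10uM}\n"
        )
        pm = PlateMap.from_file(tmp_path / "map.yaml")
        assert pm.wells["B02"] == Condition("mutant", "drug", "10uM")
        recs = _recordings(3, 1)  # wells B01..B03
        groups = apply_plate_map(recs, pm)
        assert {g: len(v) for g, v in groups.items()} == {
            "control": 1, "mutant|drug|10uM": 1, UNASSIGNED: 1,
        }
        # partition: every recording in exactly one group
        assert sum(len(v) for v in groups.values()) == len(recs)

    def test_empty_map_all_unassigned(self):
        groups = apply_plate_map(_recordings(2, 2), PlateMap({}))
        assert list(groups) == [UNASSIGNED]
        assert len(groups[UNASSIGNED]) == 4

    def test_csv_duplicate_well_rejected(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("well,genotype\nB07,wt\nB07,mut\n")
        with pytest.raises(ConfigError, match="B07"):
            PlateMap.from_file(p)

    def test_yaml_duplicate_well_rejected(self, tmp_path):
        p = tmp_path / "map.yaml"
        p.write_text("wells:\n  B07: {genotype: wt}\n  B07: {genotype: mut}\n")
        with pytest.raises(ConfigError):
            PlateMap.from_file(p)

    def test_invalid_well_label(self):
        with pytest.raises(ConfigError):
            PlateMap({"7B": Condition("wt")})


class TestExportFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "well": ["B01", "B01", "B02"],
                "fov": [0, 0, 0],
                "roi": [1, 2, 1],
                "condition": ["control", "control", "treated"],
                "frequency_hz": [0.1, 0.25, 0.0],
                "amplitude_mean": [1.5, 2.25, np.nan],
            }
        )

    def test_one_csv_per_feature_plus_combined(self, tmp_path):
        written = export_feature_tables(self._table(), tmp_path)
        names = sorted(p.name for p in written)
        assert names == ["amplitude_mean.csv", "features_combined.csv",
                         "frequency_hz.csv"]

    def test_round_trip_identical_values(self, tmp_path):
        table = self._table()
        export_feature_tables(table, tmp_path)
        back = pd.read_csv(tmp_path / "features_combined.csv")
        pd.testing.assert_frame_equal(back, table, check_dtype=False)
        per = pd.read_csv(tmp_path / "frequency_hz.csv")
        np.testing.assert_array_equal(per["value"], table["frequency_hz"])

    def test_empty_table_header_only(self, tmp_path):
        empty = self._table().iloc[0:0]
        export_feature_tables(empty, tmp_path)
        back = pd.read_csv(tmp_path / "features_combined.csv")
        assert len(back) == 0
        assert list(back.columns) == list(empty.columns)

    def test_duplicate_keys_rejected(self, tmp_path):
        tab = self._table()
        tab.loc[1, ["well", "fov", "roi"]] = ["B01", 0, 1]
        with pytest.raises(ValueError, match="duplicate"):
            export_feature_tables(tab, tmp_path)
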