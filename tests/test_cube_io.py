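"""Raster/region I/O, band bookkeeping and nearest-neighbor resampling."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from specsep.cube_io import (
    Affine,
    BandDef,
    ClassRegion,
    GridDefinition,
    Scene,
    SensorModel,
    drop_overlap_bands,
    read_regions,
    read_scene,
    resample_nearest,
    write_regions,
    write_scene,
    write_wavelength_sidecar,
)

from conftest import tiny_sensor


class TestRoundTrip:
    def test_values_wavelengths_transform_roundtrip(self, tmp_path, constant_scene):
        scene = constant_scene
        scene.values[1, 2, 3] = 0.77
        path = write_scene(scene, tmp_path / "cube.img")
        back = read_scene(path)
        np.testing.assert_array_equal(back.values, scene.values)
        np.testing.assert_allclose(
            back.sensor.wavelengths_nm, scene.sensor.wavelengths_nm, atol=0.01
        )
        assert back.transform == scene.transform
        assert back.crs == scene.crs

    def test_nodata_preserved(self, tmp_path, constant_scene):
        constant_scene.values[0, 0, :] = constant_scene.nodata
        path = write_scene(constant_scene, tmp_path / "cube.img")
        back = read_scene(path)
        assert back.nodata == constant_scene.nodata
        assert np.all(back.values[0, 0, :] == back.nodata)

    def test_detector_tags_roundtrip(self, tmp_path, hyper_sensor):
        values = np.zeros((2, 2, hyper_sensor.n_bands))
        scene = Scene(values, Affine.from_origin(0, 60, 30, 30), "EPSG:32632", hyper_sensor)
        back = read_scene(write_scene(scene, tmp_path / "h.img"))
        assert [b.detector for b in back.sensor.bands] == [
            b.detector for b in hyper_sensor.bands
        ]

    def test_empty_band_scene_rejected_on_write(self, tmp_path):
        sensor = SensorModel("empty", (), 30.0)
        with pytest.raises(ValueError):
            scene = Scene(
                np.zeros((2, 2, 0)), Affine.from_origin(0, 60, 30, 30), "x", sensor
            )
            write_scene(scene, tmp_path / "e.img")


class TestReadScene:
    def test_wavelength_count_mismatch(self, tmp_path, constant_scene):
        path = write_scene(constant_scene, tmp_path / "c.img")
        with pytest.raises(ValueError, match="wavelength count"):
            read_scene(path, wavelengths_source=[450.0, 560.0, 660.0])  # 3 for 4 bands

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_scene(tmp_path / "nope.img")

    def test_missing_crs(self, tmp_path, constant_scene):
        path = write_scene(constant_scene, tmp_path / "c.img")
        hdr = path.with_suffix(".hdr")
        text = "\n".join(
            ln for ln in hdr.read_text().splitlines() if not ln.startswith("coordinate")
        )
        hdr.write_text(text)
        with pytest.raises(ValueError, match="CRS"):
            read_scene(path)

    def test_micrometre_sidecar_converted(self, tmp_path, constant_scene):
        path = write_scene(constant_scene, tmp_path / "c.img")
        sidecar = tmp_path / "wl.csv"
        sidecar.write_text(
            "band_index,wavelength_nm\n0,0.45\n1,0.56\n2,0.66\n3,0.86\n"
        )
        with pytest.warns(UserWarning, match="micrometres"):
            back = read_scene(path, wavelengths_source=sidecar)
        np.testing.assert_allclose(
            back.sensor.wavelengths_nm, [450.0, 560.0, 660.0, 860.0]
        )

    def test_csv_sidecar_roundtrip(self, tmp_path, constant_scene):
        path = write_scene(constant_scene, tmp_path / "c.img")
        sidecar = write_wavelength_sidecar(constant_scene.sensor, tmp_path / "wl.csv")
        back = read_scene(path, wavelengths_source=sidecar)
        np.testing.assert_allclose(
            back.sensor.wavelengths_nm, constant_scene.sensor.wavelengths_nm, atol=0.01
        )


class TestRegions:
    def test_geojson_roundtrip(self, tmp_path):
        regions = [
            ClassRegion(Polygon([(0, 0), (60, 0), (60, 60), (0, 60)]), "3111", "r0"),
            ClassRegion(Polygon([(60, 0), (120, 0), (120, 60), (60, 60)]), "3121", "r1"),
        ]
        path = write_regions(regions, tmp_path / "regions.geojson")
        back = read_regions(path)
        assert [r.class_code for r in back] == ["3111", "3121"]
        assert back[0].geometry.equals(regions[0].geometry)

    def test_missing_class_code_property(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature", '
            '"geometry": {"type": "Point", "coordinates": [0, 0]}, "properties": {}}]}'
        )
        with pytest.raises(ValueError, match="class_code"):
            read_regions(path)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid"):
            ClassRegion(bowtie, "3111", "r0")


class TestDropOverlapBands:
    def test_hyper_reduces_to_230(self, hyper_sensor):
        assert drop_overlap_bands(hyper_sensor).n_bands == 230

    def test_idempotent(self, hyper_sensor):
        once = drop_overlap_bands(hyper_sensor)
        assert drop_overlap_bands(once) == once

    def test_no_overlap_is_identity(self):
        sensor = tiny_sensor([450.0, 560.0], detector="VNIR")
        assert drop_overlap_bands(sensor) == sensor

    def test_only_swir_removed_vnir_survives(self, hyper_sensor):
        after = drop_overlap_bands(hyper_sensor)
        removed_centers = set(b.center_nm for b in hyper_sensor.bands) - set(
            b.center_nm for b in after.bands if b.detector == "SWIR"
        )
        n_vnir_before = sum(b.detector == "VNIR" for b in hyper_sensor.bands)
        n_vnir_after = sum(b.detector == "VNIR" for b in after.bands)
        assert n_vnir_after == n_vnir_before
        assert sum(b.detector == "SWIR" for b in after.bands) == 173 - 9


def _grid_scene(rows, cols, pixel, origin, values, crs="EPSG:32632"):
    sensor = tiny_sensor([500.0], res=pixel)
    return Scene(
        values=np.asarray(values, dtype=float).reshape(rows, cols, 1),
        transform=Affine.from_origin(origin[0], origin[1], pixel, pixel),
        crs=crs,
        sensor=sensor,
    )


class TestResampleNearest:
    def test_identity_grid(self, constant_scene):
        target = GridDefinition(4, 4, constant_scene.transform, constant_scene.crs)
        out = resample_nearest(constant_scene, target)
        np.testing.assert_array_equal(out.values, constant_scene.values)

    def test_constant_block_stays_constant(self):
        scene = _grid_scene(3, 3, 10.0, (0.0, 30.0), np.full(9, 0.4))
        target = GridDefinition(1, 1, Affine.from_origin(0.0, 30.0, 30.0, 30.0), scene.crs)
        out = resample_nearest(scene, target)
        assert out.values[0, 0, 0] == 0.4

    def test_crs_mismatch(self, constant_scene):
        target = GridDefinition(4, 4, constant_scene.transform, "EPSG:4326")
        with pytest.raises(ValueError, match="CRS mismatch"):
            resample_nearest(constant_scene, target)

    def test_non_overlapping_grids(self, constant_scene):
        far = GridDefinition(2, 2, Affine.from_origin(1e6, 1e6, 30.0, 30.0),
                             constant_scene.crs)
        with pytest.raises(ValueError, match="overlap"):
            resample_nearest(constant_scene, far)

    def test_output_values_subset_of_input(self):
        rng = np.random.default_rng(0)
        scene = _grid_scene(12, 12, 10.0, (0.0, 120.0), rng.uniform(size=144))
        target = GridDefinition(4, 4, Affine.from_origin(0.0, 120.0, 30.0, 30.0),
                                scene.crs)
        out = resample_nearest(scene, target)
        assert set(out.values.ravel()) <= set(scene.values.ravel())

    def test_brute_force_oracle_10m_to_30m(self):
        """Each output equals the input pixel whose center is nearest the
        output center, verified by exhaustive search."""
        rng = np.random.default_rng(1)
        rows = cols = 9
        scene = _grid_scene(rows, cols, 10.0, (5.0, 95.0), rng.uniform(size=81))
        tgt_transform = Affine.from_origin(10.0, 90.0, 30.0, 30.0)
        target = GridDefinition(2, 2, tgt_transform, scene.crs)
        out = resample_nearest(scene, target)

        in_xs, in_ys = scene.transform.pixel_centers(rows, cols)
        out_xs, out_ys = tgt_transform.pixel_centers(2, 2)
        for r in range(2):
            for c in range(2):
                d2 = (in_xs - out_xs[r, c]) ** 2 + (in_ys - out_ys[r, c]) ** 2
                # tie-break toward smaller row then col = first argmin in C order
                rr, cc = np.unravel_index(np.argmin(d2), d2.shape)
                assert out.values[r, c, 0] == scene.values[rr, cc, 0]

    def test_tie_breaks_toward_smaller_index(self):
        # output center exactly between two input centers on each axis
        scene = _grid_scene(2, 2, 10.0, (0.0, 20.0), [0.1, 0.2, 0.3, 0.4])
        # center of 1x1 target = (10, 10): equidistant from all four inputs
        target = GridDefinition(1, 1, Affine.from_origin(0.0, 20.0, 20.0, 20.0),
                                scene.crs)
        out = resample_nearest(scene, target)
        assert out.values[0, 0, 0] == 0.1  # row 0, col 0 wins
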