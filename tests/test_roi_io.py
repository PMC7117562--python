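"""Image, ROI and layout I/O: formats, geometry rules, overlap detection."""

import json

import numpy as np
import pytest

from aicyto import (
    ImagePlane,
    NucleusROI,
    check_nonoverlap,
    load_image,
    load_layout,
    load_rois,
    rasterize_polygon,
    save_image,
    save_layout,
    save_rois,
)
from aicyto.roi_io import SampleEntry, StudyLayout, ValidationError

from conftest import make_plane, square_roi


class TestImageIO:
    @pytest.mark.parametrize("bit_depth,suffix", [(8, ".tif"), (16, ".tif"),
                                                  (8, ".png"), (16, ".png")])
    def test_round_trip_is_pixel_identical(self, tmp_path, rng, bit_depth, suffix):
        maxv = 2**bit_depth - 1
        px = rng.integers(0, maxv + 1, size=(20, 30))
        plane = make_plane(px, bit_depth)
        path = tmp_path / f"img{suffix}"
        save_image(path, plane)
        back = load_image(path)
        assert back.bit_depth == bit_depth
        np.testing.assert_array_equal(back.pixels, plane.pixels)

    def test_flat_grayscale_read(self, tmp_path):
        plane = make_plane(np.full((5, 5), 200), 8)
        save_image(tmp_path / "flat.tif", plane)
        back = load_image(tmp_path / "flat.tif")
        assert back.bit_depth == 8
        assert (back.pixels == 200).all()

    def test_rgb_named_channel_is_extracted_exactly(self, tmp_path, rng):
        rgb = rng.integers(0, 256, size=(10, 12, 3)).astype(np.uint8)
        import tifffile

        tifffile.imwrite(tmp_path / "rgb.tif", rgb)
        green = load_image(tmp_path / "rgb.tif", channel_policy="green")
        np.testing.assert_array_equal(green.pixels, rgb[:, :, 1])

    def test_rgb_luminance_reduction(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 0], rgb[..., 1], rgb[..., 2] = 100, 200, 50
        import tifffile

        tifffile.imwrite(tmp_path / "rgb.tif", rgb)
        plane = load_image(tmp_path / "rgb.tif")
        expect = round(0.299 * 100 + 0.587 * 200 + 0.114 * 50)
        assert (plane.pixels == expect).all()

    def test_unreadable_and_invalid_inputs(self, tmp_path):
        (tmp_path / "junk.tif").write_text("not a tiff")
        with pytest.raises(ValidationError):
            load_image(tmp_path / "junk.tif")
        with pytest.raises(ValidationError):
            ImagePlane(pixels=np.full((3, 3), 300), bit_depth=8, white_level=255.0)
        with pytest.raises(ValidationError):
            ImagePlane(pixels=np.zeros((3, 3), dtype=int), bit_depth=12,
                       white_level=255.0)


class TestPolygonROIs:
    def test_square_polygon_rasterizes_to_side_squared(self):
        roi = square_roi("a", "control", r0=2, c0=3, side=4)
        mask = roi.rasterize((10, 10))
        assert mask.sum() == 16
        assert mask[2:6, 3:7].all()

    def test_json_round_trip(self, tmp_path):
        roi = square_roi("n1", "control", 1, 1, 3)
        save_rois(tmp_path / "r.json", [roi])
        back = load_rois(tmp_path / "r.json")
        assert len(back) == 1
        assert back[0].cell_class == "control"
        np.testing.assert_array_equal(
            back[0].rasterize((8, 8)), roi.rasterize((8, 8))
        )

    def test_missing_class_tag_rejected(self, tmp_path):
        doc = {"rois": [{"id": "x", "polygon": [[0, 0], [4, 0], [4, 4]]}]}
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="missing"):
            load_rois(tmp_path / "bad.json")

    def test_duplicate_ids_rejected(self, tmp_path):
        rec = {"id": "x", "cell_class": "control",
               "polygon": [[0, 0], [4, 0], [4, 4]]}
        (tmp_path / "dup.json").write_text(json.dumps({"rois": [rec, rec]}))
        with pytest.raises(ValidationError, match="duplicate"):
            load_rois(tmp_path / "dup.json")

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [4, 4], [4, 0], [0, 4]], dtype=float)
        with pytest.raises(ValidationError, match="self-intersecting"):
            NucleusROI(id="b", cell_class="control", polygon=bowtie)

    def test_unknown_cell_class_rejected(self):
        with pytest.raises(ValidationError, match="cell_class"):
            NucleusROI(id="x", cell_class="stromal",
                       polygon=np.array([[0, 0], [4, 0], [4, 4]]))


class TestLabelMaskROIs:
    def test_label_mask_with_class_table(self, tmp_path):
        labels = np.zeros((12, 12), dtype=np.uint16)
        labels[1:4, 1:4] = 1
        labels[6:10, 6:10] = 2
        import tifffile

        tifffile.imwrite(tmp_path / "labels.tif", labels)
        (tmp_path / "classes.csv").write_text(
            "label,cell_class\n1,control\n2,epithelial\n"
        )
        rois = load_rois(tmp_path / "labels.tif", class_table=tmp_path / "classes.csv")
        assert len(rois) == 2
        assert {r.cell_class for r in rois} == {"control", "epithelial"}
        assert rois[0].rasterize((12, 12)).sum() == 9

    def test_missing_class_entry_rejected(self, tmp_path):
        labels = np.zeros((5, 5), dtype=np.uint16)
        labels[1:3, 1:3] = 7
        import tifffile

        tifffile.imwrite(tmp_path / "labels.tif", labels)
        (tmp_path / "classes.csv").write_text("label,cell_class\n1,control\n")
        with pytest.raises(ValidationError, match="label 7"):
            load_rois(tmp_path / "labels.tif", class_table=tmp_path / "classes.csv")


class TestNonOverlap:
    def test_disjoint_rois_are_ok(self):
        rois = [square_roi("a", "control", 0, 0, 3),
                square_roi("b", "epithelial", 5, 5, 3)]
        assert check_nonoverlap(rois, (10, 10)).ok

    def test_duplicated_roi_reports_its_full_pixel_set(self):
        a = square_roi("a", "control", 2, 2, 3)
        b = square_roi("b", "control", 2, 2, 3)
        report = check_nonoverlap([a, b], (10, 10))
        assert not report.ok
        assert report.n_pixels == 9
        assert all(ids == ("a", "b") for ids in report.violations.values())

    def test_overlapping_rois_error_on_load(self, tmp_path):
        recs = [
            {"id": "a", "cell_class": "control",
             "polygon": [[0.5, 0.5], [4.5, 0.5], [4.5, 4.5], [0.5, 4.5]]},
            {"id": "b", "cell_class": "control",
             "polygon": [[2.5, 2.5], [6.5, 2.5], [6.5, 6.5], [2.5, 6.5]]},
        ]
        path = tmp_path / "rois.json"
        path.write_text(json.dumps({"rois": recs}))
        with pytest.raises(ValidationError, match="overlap"):
            load_rois(path, raster_shape=(10, 10))
        with pytest.warns(UserWarning, match="overlap"):
            load_rois(path, raster_shape=(10, 10), on_overlap="warn")

    def test_report_matches_pixel_ownership_oracle(self, rng):
        shape = (40, 40)
        rois = []
        for i in range(8):
            r0, c0 = rng.integers(0, 30, size=2)
            rois.append(square_roi(f"r{i}", "control", int(r0), int(c0),
                                   int(rng.integers(3, 8))))
        report = check_nonoverlap(rois, shape)
        # brute-force per-pixel ownership count
        claimed = np.zeros(shape, dtype=int)
        for roi in rois:
            claimed += roi.rasterize(shape)
        expect = {tuple(map(int, rc)) for rc in np.argwhere(claimed >= 2)}
        assert set(report.violations) == expect
        assert report.ok == (not expect)


class TestRasterization:
    def test_polygon_and_mask_paths_agree(self, rng):
        """The same nucleus given as polygon or as its mask rasterizes alike."""
        from aicyto import mask_to_polygon

        shape = (30, 30)
        for _ in range(10):
            cy, cx = rng.uniform(8, 22, size=2)
            ry, rx = rng.uniform(3, 6, size=2)
            rr, cc = np.mgrid[0:30, 0:30]
            mask = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
            poly = mask_to_polygon(mask)
            np.testing.assert_array_equal(rasterize_polygon(poly, shape), mask)


class TestLayout:
    def test_round_trip(self, tmp_path):
        layout = StudyLayout(
            samples=(
                SampleEntry("s1", "NCT", "a.tif", "a.json"),
                SampleEntry("s2", "AC", "b.tif", "b.json"),
            ),
            conditions=("NCT", "AC"),
        )
        save_layout(tmp_path / "layout.csv", layout)
        back = load_layout(tmp_path / "layout.csv")
        assert back == layout

    def test_validation(self, tmp_path):
        with pytest.raises(ValidationError, match="unknown condition"):
            StudyLayout(
                samples=(SampleEntry("s1", "XX", "a", "b"),), conditions=("NCT",)
            )
        with pytest.raises(ValidationError, match="duplicate"):
            StudyLayout(
                samples=(
                    SampleEntry("s1", "NCT", "a", "b"),
                    SampleEntry("s1", "NCT", "c", "d"),
                ),
                conditions=("NCT",),
            )
        (tmp_path / "empty.csv").write_text("sample_id,condition,image_path,roi_path\n")
        with pytest.raises(ValidationError, match="empty"):
            load_layout(tmp_path / "empty.csv")
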