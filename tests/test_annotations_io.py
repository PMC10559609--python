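"""Annotation parsing, polygon rasterization, manifest validation, video I/O."""

import json

import numpy as np
import pytest

from laryngoscreen import (
    AnnotationFile,
    DatasetManifest,
    Frame,
    ManifestRecord,
    Modality,
    PolygonShape,
    rasterize_annotation,
    read_annotation,
    read_video_frames,
    validate_manifest,
    write_annotation,
)
from laryngoscreen.avi import read_avi, write_avi


def brute_force_raster(points, height, width):
    """Independent point-in-polygon scan at pixel centers (even-odd ray
    casting with explicit boundary-inclusive checks via shapely-free
    matplotlib paths is avoided: this is pure arithmetic)."""
    pts = np.asarray(points, float)
    n = len(pts)
    out = np.zeros((height, width), dtype=np.uint8)
    for r in range(height):
        for c in range(width):
            x, y = float(c), float(r)
            inside = False
            on_edge = False
            for i in range(n):
                x1, y1 = pts[i]
                x2, y2 = pts[(i + 1) % n]
                # boundary check: point on segment
                cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
                if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 \
                        and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
                    on_edge = True
                    break
                if (y1 > y) != (y2 > y):
                    xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xin:
                        inside = not inside
            out[r, c] = 1 if (inside or on_edge) else 0
    return out


class TestReadWriteAnnotation:
    def test_empty_shapes(self, tmp_path):
        p = tmp_path / "a.json"
        p.write_text(json.dumps({"imagePath": "x.png", "imageHeight": 4,
                                 "imageWidth": 4, "shapes": []}))
        ann = read_annotation(p)
        assert ann.shapes == []
        assert ann.image_height == 4

    def test_single_square_roundtrip(self, tmp_path):
        square = [[0, 0], [9, 0], [9, 9], [0, 9]]
        p = tmp_path / "sq.json"
        p.write_text(json.dumps({"imagePath": "x.png", "imageHeight": 12,
                                 "imageWidth": 12, "extra_key": "ignored",
                                 "shapes": [{"label": "cancer", "points": square}]}))
        ann = read_annotation(p)
        assert len(ann.shapes) == 1
        assert ann.shapes[0].label == "cancer"
        assert len(ann.shapes[0].points) == 4

    def test_two_overlapping_polygons_preserved_in_order(self, tmp_path):
        ann = AnnotationFile(
            image_path="x.png", image_height=20, image_width=20,
            shapes=[
                PolygonShape("cancer", [[0, 0], [10, 0], [10, 10], [0, 10]]),
                PolygonShape("benign", [[5, 5], [15, 5], [15, 15], [5, 15]]),
            ],
        )
        p = tmp_path / "two.json"
        write_annotation(ann, p)
        back = read_annotation(p)
        assert [s.label for s in back.shapes] == ["cancer", "benign"]
        for a, b in zip(ann.shapes, back.shapes):
            np.testing.assert_array_equal(a.points, b.points)

    def test_malformed_json_names_path(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="bad.json"):
            read_annotation(p)

    def test_polygon_under_three_vertices_rejected(self, tmp_path):
        p = tmp_path / "degenerate.json"
        p.write_text(json.dumps({"shapes": [{"label": "cancer",
                                             "points": [[0, 0], [1, 1]]}]}))
        with pytest.raises(ValueError, match="3 vertices"):
            read_annotation(p)


class TestRasterize:
    def test_empty_shapes_all_zero(self):
        ann = AnnotationFile("x", 8, 8, [])
        assert rasterize_annotation(ann, 8, 8).sum() == 0

    def test_square_covering_100_pixel_centers(self):
        # edges pass exactly through the centers of rows/cols 0 and 9:
        # boundary counts as inside, so exactly 10x10 pixels are set
        ann = AnnotationFile("x", 16, 16, [
            PolygonShape("cancer", [[0, 0], [9, 0], [9, 9], [0, 9]])])
        mask = rasterize_annotation(ann, 16, 16)
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_disjoint_squares_additive(self):
        ann = AnnotationFile("x", 32, 32, [
            PolygonShape("cancer", [[0, 0], [9, 0], [9, 9], [0, 9]]),
            PolygonShape("cancer", [[20, 20], [29, 20], [29, 29], [20, 29]]),
        ])
        assert rasterize_annotation(ann, 32, 32).sum() == 200

    def test_non_cancer_labels_excluded(self):
        ann = AnnotationFile("x", 16, 16, [
            PolygonShape("benign", [[0, 0], [9, 0], [9, 9], [0, 9]])])
        assert rasterize_annotation(ann, 16, 16).sum() == 0

    def test_out_of_bounds_vertices_clipped(self):
        ann = AnnotationFile("x", 8, 8, [
            PolygonShape("cancer", [[4, 4], [20, 4], [20, 20], [4, 20]])])
        mask = rasterize_annotation(ann, 8, 8)
        assert mask.sum() == 16  # rows/cols 4..7 only
        assert mask[4:, 4:].all()

    def test_matches_brute_force_on_random_polygons(self, rng):
        """Rasterized area equals the pixel-center point-in-polygon scan."""
        for _ in range(100):
            n_vert = int(rng.integers(3, 9))
            # random star-shaped polygon to avoid self-intersection
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radius = rng.uniform(1.5, 6.0, n_vert)
            cx, cy = rng.uniform(4, 10, 2)
            pts = np.stack([cx + radius * np.cos(angles),
                            cy + radius * np.sin(angles)], axis=1)
            pts = np.clip(pts, 0, 15)
            ann = AnnotationFile("x", 16, 16, [PolygonShape("cancer", pts)])
            got = rasterize_annotation(ann, 16, 16)
            expected = brute_force_raster(pts, 16, 16)
            np.testing.assert_array_equal(got, expected)


def _rec(pid, idx, split="train", label="benign", ann=None, modality=Modality.WLI):
    return ManifestRecord(patient_id=pid, frame_path=f"{pid}_{idx}.png",
                          annotation_path=ann, modality=modality, label=label,
                          split=split)


class TestValidateManifest:
    def test_valid_manifest_is_clean(self):
        m = DatasetManifest([_rec("P1", i) for i in range(3)])
        assert validate_manifest(m) == []

    def test_split_leakage_detected(self):
        m = DatasetManifest([_rec("P1", 0, "train"), _rec("P1", 1, "test")])
        codes = [v.code for v in validate_manifest(m)]
        assert codes == ["split_leakage"]

    def test_frame_cap_exceeded(self):
        m = DatasetManifest([_rec("P1", i) for i in range(11)])
        violations = validate_manifest(m)
        assert [v.code for v in violations] == ["frame_cap_exceeded"]
        assert violations[0].patient_id == "P1"

    def test_cancer_training_frame_requires_annotation(self):
        m = DatasetManifest([_rec("P1", 0, "train", "cancer", ann=None)])
        assert [v.code for v in validate_manifest(m)] == ["missing_annotation"]
        # same frame in the test split is fine
        m2 = DatasetManifest([_rec("P1", 0, "test", "cancer", ann=None)])
        assert validate_manifest(m2) == []

    def test_manifest_csv_roundtrip(self, tmp_path):
        m = DatasetManifest([
            _rec("P1", 0, "train", "cancer", ann="a.json"),
            _rec("P2", 0, "test", "normal", modality=Modality.NBI),
        ])
        m.to_csv(tmp_path / "m.csv")
        back = DatasetManifest.from_csv(tmp_path / "m.csv")
        assert len(back) == 2
        assert back.records[0].annotation_path == "a.json"
        assert back.records[1].annotation_path is None
        assert back.records[1].modality is Modality.NBI


class TestVideoIO:
    def test_avi_roundtrip_2s_25fps(self, tmp_path, rng):
        frames = [rng.integers(0, 256, (32, 48, 3), dtype=np.uint8)
                  for _ in range(50)]
        path = tmp_path / "clip.avi"
        write_avi(path, frames, fps=25)
        loaded, fps = read_video_frames(path)
        assert fps == 25.0
        assert len(loaded) == 50
        assert [f.frame_index for f in loaded] == list(range(50))
        np.testing.assert_array_equal(loaded[0].image, frames[0])
        np.testing.assert_array_equal(loaded[-1].image, frames[-1])

    def test_single_frame_clip(self, tmp_path):
        img = np.full((16, 16, 3), 99, dtype=np.uint8)
        path = tmp_path / "one.avi"
        write_avi(path, [img], fps=10)
        loaded, fps = read_video_frames(path)
        assert len(loaded) == 1 and loaded[0].frame_index == 0
        np.testing.assert_array_equal(loaded[0].image, img)

    def test_duration_arithmetic_75_frames_at_30fps(self, tmp_path, rng):
        frames = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
                  for _ in range(75)]
        path = tmp_path / "d.avi"
        write_avi(path, frames, fps=30)
        loaded, fps = read_video_frames(path)
        assert len(loaded) / fps == pytest.approx(2.5)

    def test_unreadable_container_raises(self, tmp_path):
        p = tmp_path / "junk.avi"
        p.write_bytes(b"this is not a RIFF file at all")
        with pytest.raises(IOError):
            read_video_frames(p)

    def test_raw_reader_rejects_non_avi(self, tmp_path):
        p = tmp_path / "x.avi"
        p.write_bytes(b"RIFF\x04\x00\x00\x00WAVE")
        with pytest.raises(IOError):
            read_avi(p)

    def test_frame_mask_shape_contract(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="mask shape"):
            Frame(image=img, modality=Modality.WLI, patient_id="p",
                  mask=np.zeros((4, 4)))
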