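"""Annotation round trips, the split protocol, augmentation consistency and
the synthetic scene generator."""

import numpy as np
import pytest

from phrfdet.data import (AnnotationRecord, CLASS_NAMES, SceneSpec, augment,
                          blur, from_voc_xml, generate_dataset, generate_scene,
                          random_crop, read_yolo_txt, rotate, rotate90,
                          split_dataset, to_voc_xml, write_yolo_txt)
from phrfdet.losses import pairwise_iou


class TestAnnotationRecord:
    def test_valid_record(self):
        r = AnnotationRecord("img", 0, (0.5, 0.5, 0.2, 0.1))
        assert r.xyxy == pytest.approx((0.4, 0.45, 0.6, 0.55))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AnnotationRecord("img", 0, (1.2, 0.5, 0.2, 0.1))

    def test_bad_class_rejected(self):
        with pytest.raises(ValueError):
            AnnotationRecord("img", 9, (0.5, 0.5, 0.2, 0.1))


class TestYoloTxt:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "img.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n")
        (rec,) = read_yolo_txt(p)
        assert rec.class_id == 0 and rec.box == (0.5, 0.5, 0.2, 0.1)

    def test_roundtrip_identity(self, tmp_path, rng):
        recs = []
        for i in range(20):
            w, h = rng.uniform(0.05, 0.3, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            recs.append(AnnotationRecord("r", int(rng.integers(0, 5)),
                                         (cx, cy, w, h)))
        p = tmp_path / "r.txt"
        write_yolo_txt(recs, p)
        back = read_yolo_txt(p)
        for a, b in zip(recs, back):
            assert a.class_id == b.class_id
            np.testing.assert_allclose(a.box, b.box, atol=1e-6)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n0 0.5 0.5\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_txt(p)

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1.2 0.5 0.2 0.1\n")
        with pytest.raises(ValueError):
            read_yolo_txt(p)


class TestVocXml:
    def test_corner_arithmetic(self):
        rec = AnnotationRecord("img", 0, (0.5, 0.5, 0.2, 0.1))
        xml = to_voc_xml([rec], (640, 640))
        recs, (w, h) = from_voc_xml(xml)
        assert (w, h) == (640, 640)
        assert b"<xmin>256</xmin>" in xml
        assert b"<ymin>288</ymin>" in xml
        assert b"<xmax>384</xmax>" in xml
        assert b"<ymax>352</ymax>" in xml

    def test_class_name_words(self):
        xml = to_voc_xml(
            [AnnotationRecord("img", i, (0.5, 0.5, 0.1, 0.1)) for i in range(5)],
            (640, 640),
        )
        for name in ("beggartick", "crabgrass", "galinsoga_quadriradiata",
                     "goosegrass", "tropic_ageratum_herb"):
            assert name.encode() in xml

    def test_roundtrip_within_one_pixel(self, rng):
        recs = []
        for i in range(10):
            w, h = rng.uniform(0.05, 0.3, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            recs.append(AnnotationRecord("x", int(rng.integers(0, 5)),
                                         (cx, cy, w, h)))
        back, _ = from_voc_xml(to_voc_xml(recs, (640, 640)))
        for a, b in zip(recs, back):
            assert np.abs(np.array(a.box) - np.array(b.box)).max() * 640 <= 1.0


class TestSplit:
    def test_canonical_986_split(self):
        s = split_dataset([f"i{k}" for k in range(986)], seed=3)
        assert (len(s.train), len(s.val), len(s.test)) == (690, 98, 198)

    def test_small_split(self):
        s = split_dataset(list(range(10)), seed=0)
        assert (len(s.train), len(s.val), len(s.test)) == (7, 1, 2)

    def test_determinism_and_seed_sensitivity(self):
        ids = [f"i{k}" for k in range(50)]
        a = split_dataset(ids, seed=5)
        b = split_dataset(ids, seed=5)
        c = split_dataset(ids, seed=6)
        assert a.train == b.train and a.val == b.val and a.test == b.test
        assert a.train != c.train

    def test_disjoint_and_covering(self):
        ids = [f"i{k}" for k in range(101)]
        s = split_dataset(ids, seed=1)
        assert set(s.train) | set(s.val) | set(s.test) == set(ids)
        assert not (set(s.train) & set(s.test))

    def test_stratified_keeps_aggregate_sizes(self):
        ids = [f"i{k}" for k in range(100)]
        labels = {i: k % 5 for k, i in enumerate(ids)}
        s = split_dataset(ids, seed=2, per_class_labels=labels, stratify=True)
        assert (len(s.train), len(s.val), len(s.test)) == (70, 10, 20)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), ratios=(0.7, 0.1, 0.1))


class TestAugment:
    def test_rotate_zero_is_identity_on_boxes(self, small_scenes):
        img, recs = small_scenes[0]
        _, out = rotate(img, recs, 0.0)
        for a, b in zip(recs, out):
            np.testing.assert_allclose(a.box, b.box, atol=1e-9)

    def test_blur_leaves_annotations_unchanged(self, small_scenes):
        img, recs = small_scenes[0]
        out_img, out = blur(img, recs, sigma=2.0)
        assert [r.box for r in out] == [r.box for r in recs]
        assert out_img.shape == img.shape

    def test_rot90_center_mapping(self, small_scenes):
        """(cx, cy) -> (cy, 1-cx) for square images, verified on pixels."""
        img, recs = small_scenes[1]
        out_img, out = rotate90(img, recs, 1)
        r, o = recs[0], out[0]
        assert o.box[0] == pytest.approx(r.box[1], abs=1e-9)
        assert o.box[1] == pytest.approx(1 - r.box[0], abs=1e-9)
        assert (o.box[2], o.box[3]) == pytest.approx((r.box[3], r.box[2]))
        # brute-force check: rotating a synthetic mask of the box matches
        size = img.shape[0]
        mask = np.zeros((size, size))
        x1, y1, x2, y2 = [int(round(v * size)) for v in r.xyxy]
        mask[y1:y2, x1:x2] = 1
        rot_mask = np.rot90(mask)
        ys, xs = np.nonzero(rot_mask)
        nx1, nx2 = xs.min() / size, (xs.max() + 1) / size
        ny1, ny2 = ys.min() / size, (ys.max() + 1) / size
        np.testing.assert_allclose(o.xyxy, (nx1, ny1, nx2, ny2), atol=1.5 / size)

    def test_crop_boxes_stay_valid_and_low_visibility_dropped(self, small_scenes,
                                                              rng):
        for img, recs in small_scenes:
            out_img, out = random_crop(img, recs, rng, scale=(0.4, 0.9))
            assert out_img.shape == img.shape
            for r in out:
                x1, y1, x2, y2 = r.xyxy
                assert -1e-6 <= x1 <= x2 <= 1 + 1e-6
                assert -1e-6 <= y1 <= y2 <= 1 + 1e-6

    def test_full_chain_determinism(self, small_scenes):
        img, recs = small_scenes[2]
        a_img, a_rec = augment(img, recs, seed=7)
        b_img, b_rec = augment(img, recs, seed=7)
        np.testing.assert_array_equal(a_img, b_img)
        assert [r.box for r in a_rec] == [r.box for r in b_rec]


class TestSceneGenerator:
    def test_single_target_scenario(self):
        img, recs = generate_scene(SceneSpec(image_size=160, n_targets=1, seed=3))
        assert len(recs) == 1

    def test_bit_identical_determinism(self):
        spec = SceneSpec(image_size=160, n_targets=3, seed=9)
        a_img, a_rec = generate_scene(spec)
        b_img, b_rec = generate_scene(spec)
        np.testing.assert_array_equal(a_img, b_img)
        assert [r.box for r in a_rec] == [r.box for r in b_rec]

    def test_occlusion_preset_guarantees_overlap(self):
        for seed in range(5):
            _, recs = generate_scene(
                SceneSpec(image_size=160, n_targets=2, occlusion=True, seed=seed)
            )
            boxes = np.array([r.xyxy for r in recs])
            m = pairwise_iou(boxes, boxes)
            assert m[~np.eye(len(boxes), dtype=bool)].max() > 0.1

    def test_overpacked_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(image_size=160, n_targets=500)

    def test_boxes_satisfy_record_invariants(self):
        for img, recs in generate_dataset(5, "multi", seed=2, image_size=120):
            for r in recs:
                x1, y1, x2, y2 = r.xyxy
                assert 0 <= x1 < x2 <= 1 and 0 <= y1 < y2 <= 1

    def test_classes_separable_by_colour_histogram(self):
        """A trivial nearest-mean colour classifier beats chance easily."""
        samples = {c: [] for c in range(5)}
        for seed in range(40):
            spec = SceneSpec(image_size=96, n_targets=1, seed=seed)
            img, recs = generate_scene(spec)
            if not recs:
                continue
            r = recs[0]
            x1, y1, x2, y2 = [int(round(v * 96)) for v in r.xyxy]
            patch = img[y1:y2, x1:x2].reshape(-1, 3).astype(float)
            samples[r.class_id].append(patch.mean(axis=0))
        train = {c: np.mean(v[: max(1, len(v) // 2)], axis=0)
                 for c, v in samples.items() if v}
        total = correct = 0
        for c, feats in samples.items():
            for f in feats[max(1, len(feats) // 2):]:
                pred = min(train, key=lambda k: np.linalg.norm(train[k] - f))
                correct += int(pred == c)
                total += 1
        assert total > 0
        assert correct / total > 0.4  # chance is 0.2 over five classes


class TestSplitThenAugment:
    def test_augmented_images_never_cross_partitions(self, small_scenes):
        from phrfdet.data import augment_split, split_dataset

        scenes_by_id = {f"s{i}": sc for i, sc in enumerate(small_scenes)}
        split = split_dataset(sorted(scenes_by_id), seed=4)
        out = augment_split(scenes_by_id, split, multiplier=3, seed=0)
        # provenance: every augmented id derives from a training id
        train_sources = {i.split("#")[0] for i, _, _ in out["train"]}
        assert train_sources == set(split.train)
        for name in ("val", "test"):
            ids = [i for i, _, _ in out[name]]
            assert all("#aug" not in i for i in ids)
            assert set(ids) == set(getattr(split, name))
        # multiplier honoured and all boxes still valid records
        assert len(out["train"]) == 3 * len(split.train)
        for _, _, recs in out["train"]:
            for r in recs:
                x1, y1, x2, y2 = r.xyxy
                assert -1e-6 <= x1 <= x2 <= 1 + 1e-6
                assert -1e-6 <= y1 <= y2 <= 1 + 1e-6

    def test_expansion_is_seed_deterministic(self, small_scenes):
        from phrfdet.data import augment_split, split_dataset

        scenes_by_id = {f"s{i}": sc for i, sc in enumerate(small_scenes)}
        split = split_dataset(sorted(scenes_by_id), seed=4)
        a = augment_split(scenes_by_id, split, multiplier=2, seed=9)
        b = augment_split(scenes_by_id, split, multiplier=2, seed=9)
        for (ia, im_a, _), (ib, im_b, _) in zip(a["train"], b["train"]):
            assert ia == ib
            np.testing.assert_array_equal(im_a, im_b)
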