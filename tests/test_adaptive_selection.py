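"""Object-variance scoring and image-selection strategies."""

import logging

import numpy as np
import pytest

from persalmap import (
    FixtureDetector,
    ImageRecord,
    InsufficientPersonsError,
    ObjectBox,
    SaliencyMap,
    VarianceTable,
    compute_variance_table,
    detect_objects,
    image_variance_row,
    object_variance,
    read_boxes_json,
    read_boxes_tsv,
    select_images,
    select_images_ispsm,
    select_images_isvf,
    select_images_random,
    write_boxes_json,
    write_boxes_tsv,
)
from persalmap.synthetic_gaze import generate_dataset, generate_scene

from conftest import random_map


def box(cat=1, r0=0, c0=0, h=2, w=2, image="img", score=1.0):
    return ObjectBox(image, cat, r0, c0, h, w, score)


class TestObjectVariance:
    def test_identical_maps_have_zero_variance(self, rng):
        m = random_map(rng)
        assert object_variance([m, m, m], box()) == pytest.approx(0.0, abs=1e-15)

    def test_two_person_single_pixel_hand_value(self):
        a = SaliencyMap("img", np.array([[0.0]]))
        b = SaliencyMap("img", np.array([[1.0]]))
        # mean 0.5, population variance (0.25 + 0.25) / 2 = 0.25
        assert object_variance([a, b], box(h=1, w=1)) == pytest.approx(0.25)

    def test_matches_triple_loop_oracle(self, rng):
        maps = [random_map(rng, (6, 6)) for _ in range(5)]
        b = box(r0=1, c0=2, h=3, w=3)
        total = 0.0
        for j in range(b.row0, b.row0 + b.height):
            for k in range(b.col0, b.col0 + b.width):
                mean = sum(m.values[j, k] for m in maps) / 5
                total += sum((m.values[j, k] - mean) ** 2 for m in maps) / 5
        expected = total / (b.height * b.width)
        assert object_variance(maps, b) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_persons_raises(self, rng):
        with pytest.raises(InsufficientPersonsError):
            object_variance([random_map(rng)], box())


class TestImageVarianceRow:
    def test_no_boxes_gives_zero_vector(self, rng):
        maps = [random_map(rng) for _ in range(3)]
        assert not image_variance_row([], maps, num_categories=4).any()

    def test_repeated_category_takes_largest_instance(self, rng):
        maps = [random_map(rng, (8, 8)) for _ in range(4)]
        b1 = box(cat=3, r0=0, c0=0, h=2, w=2)
        b2 = box(cat=3, r0=4, c0=4, h=3, w=3)
        row = image_variance_row([b1, b2], maps, num_categories=3)
        assert row[2] == pytest.approx(
            max(object_variance(maps, b1), object_variance(maps, b2))
        )
        assert not row[:2].any()

    def test_one_instance_per_category(self, rng):
        maps = [random_map(rng, (8, 8)) for _ in range(3)]
        boxes = [box(cat=c, r0=c, c0=c, h=2, w=2) for c in (1, 2, 3)]
        row = image_variance_row(boxes, maps, num_categories=3)
        for c, b in zip((1, 2, 3), boxes):
            assert row[c - 1] == pytest.approx(object_variance(maps, b))


class TestSelectImages:
    def test_top_c_ordering(self):
        table = VarianceTable(v=np.array([[0.5], [0.9], [0.1]]),
                              v_bar=np.array([0.5, 0.9, 0.1]))
        res = select_images(table, C=2)
        assert res.indices == (1, 0)
        assert res.scores == (0.9, 0.5)

    def test_ties_break_by_lower_index(self):
        table = VarianceTable(v=np.ones((3, 1)), v_bar=np.ones(3))
        assert select_images(table, C=2).indices == (0, 1)

    def test_c_equals_n_returns_all_sorted(self):
        table = VarianceTable(v=np.array([[0.2], [0.8], [0.5]]),
                              v_bar=np.array([0.2, 0.8, 0.5]))
        assert select_images(table, C=3).indices == (1, 2, 0)

    def test_c_out_of_range_raises(self):
        table = VarianceTable(v=np.ones((3, 1)), v_bar=np.ones(3))
        with pytest.raises(ValueError):
            select_images(table, C=4)


class TestVarianceTable:
    def test_row_sum_additivity(self, rng):
        maps = [[random_map(rng, (8, 8)) for _ in range(3)] for _ in range(4)]
        boxes = [
            [box(cat=int(rng.integers(1, 4)), r0=int(rng.integers(0, 5)),
                 c0=int(rng.integers(0, 5)), h=3, w=3)
             for _ in range(int(rng.integers(0, 3)))]
            for _ in range(4)
        ]
        table = compute_variance_table(boxes, maps, num_categories=3)
        assert np.allclose(table.v_bar, table.v.sum(axis=1), atol=1e-15)

    def test_scale_equivariance_preserves_ranking(self, rng):
        maps = [[random_map(rng, (8, 8)) for _ in range(4)] for _ in range(5)]
        boxes = [[box(cat=1 + n % 3, r0=n, c0=n, h=3, w=3)] for n in range(5)]
        t1 = compute_variance_table(boxes, maps, 3, normalize=None)
        scaled = [
            [SaliencyMap(m.image_id, 2.5 * m.values) for m in row] for row in maps
        ]
        t2 = compute_variance_table(boxes, scaled, 3, normalize=None)
        assert np.allclose(t2.v, 2.5**2 * t1.v, rtol=1e-12)
        assert select_images(t1, 5).indices == select_images(t2, 5).indices

    def test_pipeline_matches_nested_loop_reference(self, rng):
        # small random instances against a brute-force implementation
        for _ in range(20):
            N = int(rng.integers(2, 6))
            M = int(rng.integers(1, 5))
            P = int(rng.integers(2, 7))
            maps = [[random_map(rng, (8, 8)) for _ in range(P)] for _ in range(N)]
            boxes = [
                [box(cat=int(rng.integers(1, M + 1)), r0=int(rng.integers(0, 5)),
                     c0=int(rng.integers(0, 5)), h=int(rng.integers(1, 4)),
                     w=int(rng.integers(1, 4)))
                 for _ in range(int(rng.integers(0, 4)))]
                for _ in range(N)
            ]
            table = compute_variance_table(boxes, maps, M, normalize=None)
            ref = np.zeros((N, M))
            for n in range(N):
                for b in boxes[n]:
                    acc = 0.0
                    for j in range(b.row0, b.row0 + b.height):
                        for k in range(b.col0, b.col0 + b.width):
                            mean = sum(m.values[j, k] for m in maps[n]) / P
                            acc += sum((m.values[j, k] - mean) ** 2 for m in maps[n]) / P
                    ref[n, b.category - 1] = max(
                        ref[n, b.category - 1], acc / (b.height * b.width)
                    )
            assert np.allclose(table.v, ref, atol=1e-12)


class TestBaselineStrategies:
    def test_ispsm_identical_persons_fall_to_tiebreak(self, rng):
        m = [random_map(rng, (6, 6), image_id=f"i{n}") for n in range(3)]
        maps = [[m[n], m[n]] for n in range(3)]
        res = select_images_ispsm(maps, C=2)
        assert res.indices == (0, 1)
        assert res.scores == (0.0, 0.0)

    def test_ispsm_puts_disagreement_first(self, rng):
        # image 1: persons disagree in one region; others: identical
        flat = SaliencyMap("a", np.full((6, 6), 0.5))
        hot = np.full((6, 6), 0.5)
        hot[2:4, 2:4] = 1.0
        maps = [
            [flat, flat],
            [SaliencyMap("b", hot), flat],
            [flat, flat],
        ]
        assert select_images_ispsm(maps, C=1, normalize=None).indices == (1,)

    def test_ispsm_matches_bruteforce_oracle(self, rng):
        maps = [[random_map(rng, (5, 5)) for _ in range(4)] for _ in range(10)]
        res = select_images_ispsm(maps, C=10, normalize=None)
        scores = []
        for row in maps:
            stack = np.array([m.values for m in row])
            scores.append(stack.var(axis=0).mean())
        order = np.lexsort((np.arange(10), -np.asarray(scores)))
        assert res.indices == tuple(order)

    def test_isvf_selects_the_odd_image_out(self, rng):
        same = rng.uniform(0.4, 0.6, (8, 8, 3))
        images = [ImageRecord(f"i{k}", same.copy()) for k in range(3)]
        images.append(ImageRecord("odd", rng.uniform(0.0, 0.1, (8, 8, 3))))
        assert select_images_isvf(images, C=1).indices == (3,)

    def test_isvf_accepts_custom_feature_extractor(self, rng):
        images = [ImageRecord(f"i{k}", rng.uniform(0, 1, (4, 4, 3))) for k in range(4)]
        feats = {f"i{k}": np.eye(4)[k] for k in range(4)}
        res = select_images_isvf(images, C=2, feature_extractor=lambda im: feats[im.image_id])
        assert len(res.indices) == 2  # orthogonal features: all equally diverse

    def test_random_selection_is_seeded_and_distinct(self):
        a = select_images_random(10, 4, seed=5)
        b = select_images_random(10, 4, seed=5)
        assert a.indices == b.indices
        assert len(set(a.indices)) == 4


class TestDetectObjects:
    def test_fixture_detector_roundtrip(self):
        img, boxes = generate_scene(32, 32, n_objects=4, n_categories=3, seed=1)
        det = FixtureDetector({img.image_id: boxes})
        assert detect_objects(img, det) == boxes

    def test_empty_image_gives_empty_list(self):
        img, _ = generate_scene(16, 16, n_objects=0, n_categories=3, seed=0)
        assert detect_objects(img, FixtureDetector({})) == []

    def test_out_of_bounds_box_is_clipped_with_warning(self, rng, caplog):
        img = ImageRecord("i", rng.uniform(0, 1, (10, 10, 3)))
        det = lambda image: [(1, (6, 6, 6, 6), 0.9)]  # exceeds bounds by 2 px
        with caplog.at_level(logging.WARNING, logger="persalmap"):
            out = detect_objects(img, det)
        assert out == [ObjectBox("i", 1, 6, 6, 4, 4, 0.9)]
        assert any("clipped" in r.message for r in caplog.records)

    def test_low_confidence_boxes_are_dropped(self, rng):
        img = ImageRecord("i", rng.uniform(0, 1, (10, 10, 3)))
        det = lambda image: [(1, (0, 0, 3, 3), 0.2), (2, (4, 4, 3, 3), 0.8)]
        out = detect_objects(img, det, min_confidence=0.5)
        assert [b.category for b in out] == [2]


class TestAisDiscrimination:
    def test_ais_prefers_images_with_discriminative_objects(self):
        # persons differ only on categories {1, 2}: images containing those
        # objects should dominate the selection
        good = 0
        trials = 50
        from persalmap.synthetic_gaze import ClusterSpec

        for seed in range(trials):
            ds = generate_dataset(
                P=8, N=20, M=6, seed=seed,
                cluster_spec=ClusterSpec(n_clusters=2, active_categories=(1, 2)),
            )
            boxes = [ds.boxes[img.image_id] for img in ds.images]
            maps = [[ds.psms[p][n] for p in range(8)] for n in range(20)]
            table = compute_variance_table(boxes, maps, 6)
            top = select_images(table, C=3).indices
            has_active = [
                any(b.category in (1, 2) for b in boxes[n]) for n in range(20)
            ]
            if sum(has_active) >= 3 and all(has_active[n] for n in top):
                good += 1
            elif sum(has_active) < 3:
                trials -= 1  # degenerate draw: not enough discriminative images
        assert good / trials >= 0.95


class TestBoxIO:
    def test_json_roundtrip(self, tmp_path):
        img, boxes = generate_scene(24, 24, n_objects=3, n_categories=4, seed=2)
        path = tmp_path / "boxes.json"
        write_boxes_json(path, {img.image_id: boxes})
        back = read_boxes_json(path)
        assert back[img.image_id] == boxes

    def test_tsv_roundtrip(self, tmp_path):
        img, boxes = generate_scene(24, 24, n_objects=3, n_categories=4, seed=3)
        path = tmp_path / "boxes.tsv"
        write_boxes_tsv(path, {img.image_id: boxes})
        back = read_boxes_tsv(path)
        assert back[img.image_id] == boxes
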