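"""Dataset tooling: label I/O, splitting, augmentation, mosaic, synthesis."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from smlsyolo.data import (DatasetManifest, ImageSample, InstanceAnnotation,
                           LabelParseError, SynthConfig, augment_sixfold,
                           generate_synthetic_fundus,
                           generate_synthetic_samples, hflip, load_samples,
                           mask_to_box, mosaic_augment, polygon_to_mask,
                           read_labels, rotate90, split_dataset, vflip,
                           write_labels)


class TestLabelsIO:
    def test_parse_basic(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.1 0.1 0.5 0.1 0.3 0.6\n")
        anns = read_labels(p)
        assert len(anns) == 1
        assert anns[0].class_id == 0
        assert anns[0].polygon.shape == (3, 2)

    @pytest.mark.parametrize("line", [
        "0 0.1 0.1 0.5",            # only two vertices
        "0 0.1 0.1 0.5 0.1 0.3",    # odd coordinate count
        "0 0.1 0.1 1.5 0.1 0.3 0.6",  # out of range
        "-1 0.1 0.1 0.5 0.1 0.3 0.6",  # negative class
        "x 0.1 0.1 0.5 0.1 0.3 0.6",   # unparseable
    ])
    def test_parse_errors_name_line(self, tmp_path, line):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.1 0.1 0.5 0.1 0.3 0.6\n" + line + "\n")
        with pytest.raises(LabelParseError, match=":2"):
            read_labels(p)

    def test_round_trip(self, tmp_path, synth_samples):
        for s in synth_samples:
            p = tmp_path / f"{s.id}.txt"
            write_labels(s.instances, p)
            back = read_labels(p)
            assert len(back) == len(s.instances)
            for a, b in zip(s.instances, back):
                assert a.class_id == b.class_id
                assert np.allclose(a.polygon, b.polygon, atol=1e-6)


class TestSplit:
    def test_paper_sizes(self):
        sp = split_dataset([str(i) for i in range(795)], 0.9, seed=0)
        assert (len(sp.train), len(sp.val)) == (716, 79)

    @pytest.mark.parametrize("n,expected", [(10, (9, 1)), (1, (1, 0))])
    def test_ceiling_rule(self, n, expected):
        sp = split_dataset([str(i) for i in range(n)], 0.9, seed=1)
        assert (len(sp.train), len(sp.val)) == expected

    def test_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(137)]
        sp = split_dataset(ids, 0.7, seed=5)
        assert set(sp.train) | set(sp.val) == set(ids)
        assert not set(sp.train) & set(sp.val)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(50)]
        a = split_dataset(ids, 0.9, seed=9)
        b = split_dataset(ids, 0.9, seed=9)
        assert a.train == b.train and a.val == b.val

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            split_dataset([], 0.9, 0)


class TestSixfold:
    def test_seven_times_count(self, synth_samples):
        out = augment_sixfold(synth_samples, seed=0)
        assert len(out) == 7 * len(synth_samples)

    def test_paper_counts(self):
        # one blank-ish sample per id; counts depend only on cardinality
        tri = InstanceAnnotation(0, [[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
        img = np.full((32, 32, 3), 60, np.uint8)
        train = [ImageSample(f"t{i}", img, [tri]) for i in range(716)]
        val = [ImageSample(f"v{i}", img, [tri]) for i in range(79)]
        assert len(augment_sixfold(train, seed=0)) == 5012
        assert len(augment_sixfold(val, seed=0)) == 553

    def test_hflip_involution(self, synth_samples):
        s = synth_samples[0]
        back = hflip(hflip(s))
        assert np.array_equal(back.image, s.image)
        for a, b in zip(s.instances, back.instances):
            assert np.allclose(a.polygon, b.polygon)

    def test_geometric_transforms_move_masks_with_pixels(self, synth_samples):
        s = synth_samples[0]
        h, w = s.image.shape[:2]
        for tf in (hflip, vflip, lambda x: rotate90(x, 1),
                   lambda x: rotate90(x, 2)):
            t = tf(s)
            th, tw = t.image.shape[:2]
            for a, b in zip(s.instances, t.instances):
                # transformed polygon area is preserved by flips/rotations
                assert a.mask(h, w).sum() == pytest.approx(
                    b.mask(th, tw).sum(), rel=0.05)

    def test_photometric_transforms_keep_polygons(self, synth_samples):
        out = augment_sixfold([synth_samples[0]], seed=0)
        orig = synth_samples[0]
        for variant in out:
            if variant.id.endswith(("_histeq", "_gray", "_lincol")):
                for a, b in zip(orig.instances, variant.instances):
                    assert np.array_equal(a.polygon, b.polygon)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            augment_sixfold([], 0)


class TestMosaic:
    def test_fixed_center_quadrants(self, synth_samples):
        s = synth_samples[0]
        out = mosaic_augment([s] * 4, 128, seed=0, center=(64, 64))
        assert out.image.shape == (128, 128, 3)
        # each quadrant holds one scaled copy: quadrants are identical
        q = [out.image[:64, :64], out.image[:64, 64:],
             out.image[64:, :64], out.image[64:, 64:]]
        assert all(np.array_equal(q[0], qi) for qi in q[1:])
        assert len(out.instances) == 4 * len(s.instances)

    def test_area_ratio_under_tile_transform(self):
        tri = InstanceAnnotation(0, [[0.2, 0.2], [0.8, 0.2], [0.5, 0.8]])
        img = np.zeros((100, 100, 3), np.uint8)
        s = ImageSample("a", img, [tri])
        out = mosaic_augment([s] * 4, 200, seed=0, center=(50, 50))
        # first tile: 50x50 quadrant of a 200 canvas -> normalised area
        # scales by (qw * qh) / S^2 = 2500 / 40000 = 1/16
        def area(poly):
            x, y = poly[:, 0], poly[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        a0 = area(tri.polygon)
        a1 = area(out.instances[0].polygon)
        assert a1 == pytest.approx(a0 / 16, rel=1e-9)

    def test_wrong_count_and_size(self, synth_samples):
        with pytest.raises(ValueError):
            mosaic_augment(synth_samples[:3], 128)
        with pytest.raises(ValueError):
            mosaic_augment(synth_samples[:4], 0)


class TestSynthetic:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SynthConfig(n_images=4, image_size=64, seed=7)
        h = []
        for sub in ("a", "b"):
            m = generate_synthetic_fundus(cfg, tmp_path / sub)
            digest = hashlib.md5()
            for rel in m.images + m.labels:
                digest.update((tmp_path / sub / rel).read_bytes())
            h.append(digest.hexdigest())
        assert h[0] == h[1]

    def test_contract_single_image(self, tmp_path):
        cfg = SynthConfig(n_images=1, image_size=256, seed=1)
        m = generate_synthetic_fundus(cfg, tmp_path)
        assert len(m.images) == len(m.labels) == 1
        samples = load_samples(m)
        assert samples[0].image.shape == (256, 256, 3)
        assert len(samples[0].instances) >= 1

    def test_emitted_polygons_reproduce_internal_masks(self, tmp_path):
        cfg = SynthConfig(n_images=3, image_size=128, seed=11)
        m = generate_synthetic_fundus(cfg, tmp_path)
        reread = load_samples(m)
        internal = generate_synthetic_samples(cfg)
        for a, b in zip(reread, internal):
            assert len(a.instances) == len(b.instances)
            for ia, ib in zip(a.instances, b.instances):
                assert np.array_equal(ia.mask(128, 128), ib.mask(128, 128))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SynthConfig(n_images=-1)
        with pytest.raises(ValueError):
            SynthConfig(n_classes=3)

    def test_two_class_mode_emits_valid_ids(self):
        samples = generate_synthetic_samples(
            SynthConfig(n_images=6, image_size=96, n_classes=2, seed=2))
        ids = {a.class_id for s in samples for a in s.instances}
        assert ids <= {0, 1}

    def test_label_files_reparse_fuzz(self, tmp_path):
        """Every emitted label file re-parses without error (>=100 samples)."""
        cfg = SynthConfig(n_images=100, image_size=64, seed=23)
        m = generate_synthetic_fundus(cfg, tmp_path)
        total = 0
        for rel in m.labels:
            anns = read_labels(tmp_path / rel)
            total += len(anns)
            for a in anns:
                assert a.mask(64, 64).sum() > 0
        assert total >= 100

    def test_polygon_box_consistency(self, synth_samples):
        """polygon -> mask -> box equals polygon -> box (within a pixel)."""
        h = w = 96
        for s in synth_samples:
            for a in s.instances:
                mb = mask_to_box(a.mask(h, w))
                x1, y1, x2, y2 = a.box
                assert mb is not None
                assert abs(mb[0] - x1 * w) <= 1.5
                assert abs(mb[1] - y1 * h) <= 1.5
                assert abs(mb[2] - x2 * w) <= 1.5
                assert abs(mb[3] - y2 * h) <= 1.5


class TestRasteriser:
    def test_half_square(self):
        # unit square occupying the left half -> exactly half the pixels
        poly = np.array([[0, 0], [0.5, 0], [0.5, 1], [0, 1]])
        mask = polygon_to_mask(poly, 10, 10)
        assert mask.sum() == 50
        assert mask[:, :5].all() and not mask[:, 5:].any()

    def test_pixel_centre_rule(self):
        # polygon covering x in [0, 0.04): centre of pixel 0 is 0.005 (in)
        poly = np.array([[0, 0], [0.04, 0], [0.04, 1], [0, 1]])
        mask = polygon_to_mask(poly, 10, 100)
        assert mask[:, :4].all() and not mask[:, 4:].any()
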