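"""Phantom generator invariants and archive-format readers."""

import io
import os

import numpy as np
import pytest
from scipy import ndimage

from mammopt.datasets import (
    MIASRecord,
    PhantomConfig,
    _breast_region,
    generate_phantoms,
    load_image_pairs,
    read_mias_metadata,
    write_manifest,
)


class TestPhantomGenerator:
    def test_byte_identical_regeneration(self):
        cfg = PhantomConfig(size=32, n_samples=9, seed=11)
        a, b = generate_phantoms(cfg), generate_phantoms(cfg)
        for sa, sb in zip(a, b):
            assert sa.label == sb.label
            assert np.array_equal(sa.image, sb.image)
            assert np.array_equal(sa.mask, sb.mask)

    def test_mask_label_consistency(self, phantoms64):
        for s in phantoms64:
            if s.label == "normal":
                assert s.mask.sum() == 0
            else:
                assert s.mask.sum() > 0

    def test_masks_inside_breast_region(self, phantoms64):
        region = _breast_region(64)
        for s in phantoms64:
            assert np.all(s.mask.astype(bool) <= region)

    def test_images_bounded(self, phantoms64):
        for s in phantoms64[:20]:
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0

    def test_benign_mask_single_component_with_plausible_area(self, phantoms64):
        cfg = PhantomConfig(size=64)
        rmin, rmax = cfg.lesion_radius_range
        lo = 0.25 * np.pi * rmin ** 2
        hi = 1.5 * np.pi * rmax ** 2
        for s in phantoms64:
            if s.label != "benign":
                continue
            _, n_comp = ndimage.label(s.mask)
            assert n_comp == 1
            assert lo <= s.mask.sum() <= hi

    def test_malignant_masks_have_rougher_boundaries(self, phantoms64):
        from skimage.measure import perimeter

        ratios = {"benign": [], "malignant": []}
        for s in phantoms64:
            if s.label in ratios:
                ratios[s.label].append(perimeter(s.mask) / s.mask.sum())
        assert np.mean(ratios["malignant"]) > np.mean(ratios["benign"])

    def test_lesion_contrast_separability(self, phantoms64):
        # noiseless lesion lift recorded at generation time
        cfg = PhantomConfig(size=64)
        for s in phantoms64:
            if s.label != "normal":
                assert s.provenance["lesion_mean_lift"] >= cfg.contrast / 2

    def test_class_mix_respected(self, phantoms64):
        from collections import Counter

        counts = Counter(s.label for s in phantoms64)
        assert sum(counts.values()) == 100
        assert all(abs(c - 100 / 3) <= 1 for c in counts.values())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PhantomConfig(class_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            PhantomConfig(size=64, lesion_radius_range=(10, 20))

    def test_manifest_roundtrip(self, tmp_path):
        import pandas as pd

        samples = generate_phantoms(PhantomConfig(size=32, n_samples=4, seed=0))
        path = write_manifest(samples, tmp_path, seed=0)
        df = pd.read_csv(path)
        assert list(df.columns) == ["sample_id", "label", "path_image",
                                    "path_mask", "seed"]
        assert len(df) == 4
        assert all(os.path.exists(p) for p in df["path_image"])


class TestMIASMetadata:
    def test_full_line(self):
        (rec,) = read_mias_metadata(io.StringIO(
            "mdb001 G CIRC B 535 425 197\n").readlines())
        assert rec == MIASRecord("mdb001", "G", "CIRC", "B", 535, 425, 197)

    def test_normal_line_has_absent_fields(self):
        (rec,) = read_mias_metadata(["mdb003 D NORM"])
        assert rec.severity is None and rec.x is None and rec.radius is None

    def test_out_of_bounds_coordinate_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            read_mias_metadata(["mdb001 G CIRC B 2000 425 197"])

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_mias_metadata(["mdb001 G CIRC B 535 425 197", "a b c d e"])


class TestImagePairs:
    @pytest.fixture()
    def pgm_dir(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "mdb001.pgm",
                    np.full((64, 64), 255, dtype=np.uint8))
        iio.imwrite(tmp_path / "mdb002.pgm",
                    np.full((64, 64), 0, dtype=np.uint8))
        return tmp_path

    def test_rescale_to_unit_range(self, pgm_dir):
        recs = [MIASRecord("mdb001", "G", "NORM")]
        ((img, mask, label),) = load_image_pairs(pgm_dir, recs)
        assert img.max() == img.min() == 1.0
        assert label == "normal" and mask.sum() == 0

    def test_disc_rasterization_area(self, pgm_dir):
        recs = [MIASRecord("mdb001", "G", "CIRC", "B", 32, 32, 10)]
        ((_, mask, label),) = load_image_pairs(pgm_dir, recs)
        assert label == "benign"
        assert 285 <= mask.sum() <= 330  # pi * 10^2 within rasterization slack

    def test_vertical_origin_convention(self, pgm_dir):
        # y measured from the bottom: a small y must land near the last rows
        recs = [MIASRecord("mdb001", "G", "CIRC", "M", 32, 5, 3)]
        ((_, mask, _),) = load_image_pairs(pgm_dir, recs)
        rows = np.nonzero(mask.any(axis=1))[0]
        assert rows.mean() > 48
        recs_flipped = [MIASRecord("mdb001", "G", "CIRC", "M", 32, 5, 3)]
        ((_, m2, _),) = load_image_pairs(pgm_dir, recs_flipped,
                                         origin_bottom_left=False)
        assert np.nonzero(m2.any(axis=1))[0].mean() < 16

    def test_missing_file_names_the_reference(self, pgm_dir):
        recs = [MIASRecord("mdb001", "G", "NORM"), MIASRecord("mdb999", "G", "NORM")]
        with pytest.raises(FileNotFoundError, match="mdb999"):
            load_image_pairs(pgm_dir, recs)
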