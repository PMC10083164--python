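"""Phantom generator: reflectivity maps, multi-look speckle statistics,
dataset round-trips."""

import numpy as np
import pytest

from octpt import phantom as ph
from octpt.phantom import (PhantomSpec, PresetProfile, BScanImage,
                           make_reflectivity_map, simulate_bscan,
                           generate_dataset, sample_phantom_spec,
                           PhantomError)


def flat_spec(height=20, width=16, boundaries=(), refls=(), bg=0.05):
    bounds = tuple(np.full(width, b, float) for b in boundaries)
    return PhantomSpec(height=height, width=width, layer_boundaries=bounds,
                       layer_reflectivities=refls,
                       background_reflectivity=bg)


class TestReflectivityMap:
    def test_single_layer_constant(self):
        spec = flat_spec(boundaries=(0.0,), refls=(0.5,))
        np.testing.assert_array_equal(make_reflectivity_map(spec),
                                      np.full((20, 16), 0.5))

    def test_two_layer_boundary_at_row_10(self):
        spec = flat_spec(boundaries=(0.0, 10.0), refls=(0.8, 0.4))
        out = make_reflectivity_map(spec)
        assert np.all(out[:10] == 0.8)
        assert np.all(out[10:] == 0.4)

    def test_background_above_first_boundary(self):
        spec = flat_spec(boundaries=(5.0,), refls=(0.5,), bg=0.05)
        out = make_reflectivity_map(spec)
        assert np.all(out[:5] == 0.05)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        spec = sample_phantom_spec(rng, 32, 32)
        np.testing.assert_array_equal(make_reflectivity_map(spec),
                                      make_reflectivity_map(spec))

    def test_crossing_boundaries_rejected(self):
        with pytest.raises(PhantomError, match="cross"):
            flat_spec(boundaries=(10.0, 8.0), refls=(0.8, 0.4))

    def test_background_must_be_darkest(self):
        with pytest.raises(PhantomError, match="background"):
            flat_spec(boundaries=(5.0,), refls=(0.5,), bg=0.6)


class TestSimulateBScan:
    def test_single_look_exponential_statistics(self):
        # unit-mean exponential speckle: mean == map value, mean^2/var == 1;
        # low reflectivity keeps the [0, 1] clipping out of play
        refl = np.full((120, 120), 0.05)
        preset = PresetProfile("one", looks=1, slices=1, field_deg=(1, 1),
                               log_compress=False)
        img = simulate_bscan(refl, preset, seed=0, log_compress=False)
        px = img.pixels
        n = px.size
        assert abs(px.mean() - 0.05) < 4 * 0.05 / np.sqrt(n)
        enl = px.mean() ** 2 / px.var(ddof=1)
        assert abs(enl - 1.0) < 3 * np.sqrt(20.0 / n)  # ~3 SE of the ENL estimate
        assert px.max() < 1.0

    def test_variance_shrinks_with_looks(self):
        refl = np.full((80, 80), 0.3)
        variances = []
        for looks in (1, 9, 25):
            preset = PresetProfile(f"l{looks}", looks=looks, slices=1,
                                   field_deg=(1, 1))
            img = simulate_bscan(refl, preset, seed=3, log_compress=False)
            variances.append(img.pixels.var())
        assert variances[0] > variances[1] > variances[2]

    def test_mean_preservation(self):
        rng = np.random.default_rng(5)
        spec = sample_phantom_spec(rng, 48, 48)
        refl = make_reflectivity_map(spec)
        acc = np.zeros_like(refl)
        reps = 50
        preset = PresetProfile("l4", looks=4, slices=1, field_deg=(1, 1))
        for r in range(reps):
            raw = refl * np.mean([np.random.default_rng(1000 + r * 4 + k)
                                  .exponential(1.0, refl.shape)
                                  for k in range(4)], axis=0)
            acc += raw
        # direct Monte-Carlo check of the model: E[I] == reflectivity map
        mc_err = np.abs(acc / reps - refl).mean()
        assert mc_err < 0.05

    def test_seed_determinism(self):
        refl = np.full((32, 32), 0.5)
        a = simulate_bscan(refl, ph.MACULAR_CUBE, seed=11)
        b = simulate_bscan(refl, ph.MACULAR_CUBE, seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_invalid_looks_rejected(self):
        with pytest.raises(PhantomError):
            PresetProfile("bad", looks=0, slices=1, field_deg=(1, 1))

    def test_class_separation_background_variance(self):
        """Cube (9 looks) background variance strictly exceeds Seven Lines
        (25 looks) on identical maps."""
        rng = np.random.default_rng(9)
        diffs = []
        for i in range(10):
            spec = sample_phantom_spec(rng, 64, 64)
            refl = make_reflectivity_map(spec)
            roi, bg = ph.auto_annotation_rects(spec)
            cube = simulate_bscan(refl, ph.MACULAR_CUBE, seed=100 + i)
            seven = simulate_bscan(refl, ph.SEVEN_LINES, seed=200 + i)
            r, c, h, w = bg
            diffs.append(cube.pixels[r:r + h, c:c + w].var()
                         - seven.pixels[r:r + h, c:c + w].var())
        assert np.mean(diffs) > 0
        assert np.sum(np.array(diffs) > 0) >= 9


class TestBScanImage:
    def test_rejects_out_of_range(self):
        with pytest.raises(PhantomError):
            BScanImage(np.full((4, 4), 1.5), "macular_cube", "original")

    def test_rejects_bad_provenance(self):
        with pytest.raises(PhantomError):
            BScanImage(np.zeros((4, 4)), "macular_cube", "downloaded")


class TestGenerateDataset:
    def test_counts_and_roundtrip(self, tmp_path):
        rows = generate_dataset(tmp_path, 3, seed=0, height=48, width=48)
        assert len(rows) == 6
        assert len(list(tmp_path.glob("*.png"))) == 6
        back = ph.load_manifest(tmp_path / "manifest.csv")
        assert [r["path"] for r in back] == [r["path"] for r in rows]
        assert [r["preset"] for r in back] == [r["preset"] for r in rows]
        assert all(r["provenance"] == "original" for r in back)
        imgs = ph.load_dataset(tmp_path / "manifest.csv")
        assert len(imgs) == 6
        assert all(im.shape == (48, 48) for im in imgs)

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        generate_dataset(tmp_path / "a", 2, seed=5, height=32, width=32)
        generate_dataset(tmp_path / "b", 2, seed=5, height=32, width=32)
        for name in ("manifest.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
        # and the images themselves
        for p in sorted((tmp_path / "a").glob("*.png")):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_paired_mode_shares_anatomy(self, tmp_path):
        generate_dataset(tmp_path, 2, seed=1, height=32, width=32, paired=True,
                         log_compress=False)
        rows = ph.load_manifest(tmp_path / "manifest.csv")
        cube = [r for r in rows if r["preset"] == "macular_cube"]
        seven = [r for r in rows if r["preset"] == "seven_lines"]
        assert cube[0]["bg_rect"] == seven[0]["bg_rect"]
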