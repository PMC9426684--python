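"""Radiomics extraction checked against brute-force and skimage oracles,
frame selection, and the redundancy/significance feature filters."""

import numpy as np
import pandas as pd
import pytest

from cinescar.phantom import CAVITY, MYOCARDIUM
from cinescar.radiomics import (
    RadiomicsConfig,
    RedundancyFilter,
    SignificanceFilter,
    extract_radiomics_row,
    firstorder_features,
    glrlm_features,
    glrlm_matrix,
    normalize_intensity,
    redundancy_filter,
    resample_inplane,
    select_frames_ed_es_mid,
    shape2d_features,
    significance_filter,
)


class TestResample:
    def test_identity_spacing_unchanged(self, rng):
        img = rng.random((20, 20))
        out, _ = resample_inplane(img, (img > 0.5).astype(int), (1.9, 1.9), 1.9)
        assert np.allclose(out, img, atol=1e-6)

    def test_constant_preserved(self):
        img = np.full((25, 25), 3.7)
        out, _ = resample_inplane(img, np.ones((25, 25), int), (1.3, 1.3), 1.9)
        assert np.allclose(out, 3.7)

    def test_total_intensity_conserved(self, rng):
        import scipy.ndimage as ndi

        img = ndi.gaussian_filter(rng.normal(0, 1, (38, 38)), 4) + 2
        out, _ = resample_inplane(img, (img > 0).astype(int), (1.0, 1.0), 1.9)
        total_in = img.sum() * 1.0
        total_out = out.sum() * 1.9**2
        assert abs(total_out / total_in - 1) < 0.005

    def test_mask_labels_preserved(self, rng):
        mask = rng.integers(0, 4, (30, 30))
        _, out_mask = resample_inplane(rng.random((30, 30)), mask, (1.2, 1.2), 1.9)
        assert set(np.unique(out_mask)).issubset(set(np.unique(mask)))

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resample_inplane(np.ones((4, 4)), np.ones((4, 4)), (1.0, 1.0), 0.0)


class TestNormalizeIntensity:
    def test_ramp_spans_all_levels(self):
        img = np.linspace(0, 1, 1024).reshape(32, 32)
        levels, degenerate = normalize_intensity(img, np.ones((32, 32)))
        assert levels.min() == 0
        assert levels.max() == 255
        assert not degenerate

    def test_constant_image_degenerate(self):
        levels, degenerate = normalize_intensity(np.full((8, 8), 2.0), np.ones((8, 8)))
        assert degenerate
        assert np.all(levels == 0)

    def test_affine_intensity_invariance(self, rng):
        img = rng.random((16, 16))
        mask = np.ones((16, 16))
        base, _ = normalize_intensity(img, mask)
        scaled, _ = normalize_intensity(3.5 * img + 11.0, mask)
        assert np.array_equal(base, scaled)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.ones((4, 4)), np.zeros((4, 4)))


class TestShapeFeatures:
    def disk(self, radius=20, n=64):
        yy, xx = np.mgrid[:n, :n]
        return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius**2

    def test_disk_limits(self):
        feats = shape2d_features(self.disk())
        assert 0.95 <= feats["sphericity"] <= 1.0
        assert feats["major_axis_length"] == pytest.approx(feats["minor_axis_length"], rel=0.02)

    def test_single_pixel_defined(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        feats = shape2d_features(m)
        assert feats["perimeter"] > 0
        assert np.isfinite(feats["sphericity"])

    def test_rectangle_moments_and_diameter(self):
        m = np.zeros((60, 60), bool)
        m[10:20, 10:50] = True  # 10 x 40
        feats = shape2d_features(m)
        assert feats["major_axis_length"] / feats["minor_axis_length"] == pytest.approx(
            4.0, rel=0.05
        )
        assert abs(feats["maximum_diameter"] - np.hypot(10, 40)) < 1.5

    def test_axes_match_skimage_regionprops(self, rng):
        from skimage.measure import regionprops

        blob = rng.random((40, 40)) > 0.6
        blob[15:25, 10:30] = True
        rp = regionprops(blob.astype(int))[0]
        feats = shape2d_features(blob)
        assert feats["major_axis_length"] == pytest.approx(rp.axis_major_length, abs=1e-6)
        assert feats["minor_axis_length"] == pytest.approx(rp.axis_minor_length, abs=1e-6)

    def test_translation_and_rot90_invariance(self):
        m = np.zeros((50, 50), bool)
        m[5:15, 20:40] = True
        base = shape2d_features(m)
        shifted = np.roll(m, (7, -6), axis=(0, 1))
        rotated = np.rot90(m)
        for other in (shifted, rotated):
            feats = shape2d_features(other)
            for key in base:
                assert feats[key] == pytest.approx(base[key], abs=1e-9), key

    def test_spacing_scales_lengths(self):
        m = self.disk()
        a = shape2d_features(m, spacing_mm=1.0)
        b = shape2d_features(m, spacing_mm=1.9)
        assert b["perimeter"] == pytest.approx(a["perimeter"] * 1.9)
        assert b["sphericity"] == pytest.approx(a["sphericity"])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape2d_features(np.zeros((4, 4), bool))


class TestFirstOrder:
    def test_constant_closed_form(self):
        img = np.full((10, 10), 3.0)
        feats = firstorder_features(img, np.ones((10, 10)), pixel_area_mm2=3.61)
        assert feats["energy"] == pytest.approx(900.0)
        assert feats["total_energy"] == pytest.approx(3249.0)
        assert feats["mean"] == 3.0
        assert feats["range"] == 0.0
        assert feats["rms"] == pytest.approx(3.0)

    def test_percentiles_match_oracle(self):
        img = np.arange(1, 101, dtype=float).reshape(10, 10)
        feats = firstorder_features(img, np.ones((10, 10)))
        assert feats["median"] == pytest.approx(50.5)
        assert feats["p90"] == pytest.approx(np.percentile(np.arange(1, 101), 90))
        assert feats["p10"] == pytest.approx(np.percentile(np.arange(1, 101), 10))

    def test_mask_locality(self, rng):
        img = rng.random((12, 12))
        mask = np.zeros((12, 12))
        mask[:6] = 1
        feats = firstorder_features(img, mask)
        img2 = img.copy()
        img2[6:] = 999.0  # outside the mask
        assert firstorder_features(img2, mask) == feats

    def test_brute_force_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        mask = rng.random((16, 16)) > 0.4
        feats = firstorder_features(img, mask, pixel_area_mm2=2.0)
        vals = sorted(img[i, j] for i, j in np.argwhere(mask))
        energy = sum(v * v for v in vals)
        assert feats["energy"] == pytest.approx(energy, abs=1e-9)
        assert feats["total_energy"] == pytest.approx(2.0 * energy, abs=1e-9)
        assert feats["maximum"] == max(vals)
        assert feats["rms"] == pytest.approx(np.sqrt(energy / len(vals)), abs=1e-12)


def glrlm_brute_force(levels, mask, angle):
    """Independent run enumeration: walk every line, split runs manually."""
    steps = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = steps[angle]
    rows, cols = levels.shape
    visited = set()
    counts = {}
    for r0 in range(rows):
        for c0 in range(cols):
            # only start from cells with no predecessor on this line
            if (r0 - dr, c0 - dc) not in visited and not (
                0 <= r0 - dr < rows and 0 <= c0 - dc < cols
            ):
                run = []
                r, c = r0, c0
                while 0 <= r < rows and 0 <= c < cols:
                    visited.add((r, c))
                    run.append((levels[r, c], bool(mask[r, c])))
                    r, c = r + dr, c + dc
                val, length = None, 0
                for v, ok in run:
                    if ok and v == val:
                        length += 1
                    else:
                        if length:
                            counts[(val, length)] = counts.get((val, length), 0) + 1
                        val, length = (v, 1) if ok else (None, 0)
                if length:
                    counts[(val, length)] = counts.get((val, length), 0) + 1
    return counts


class TestGlrlm:
    def test_single_run(self):
        levels = np.array([[5, 5, 5]])
        feats = glrlm_features(levels, np.ones((1, 3)), angles=(0,))
        assert feats["gray_level_nonuniformity"] == 1.0
        assert feats["run_length_nonuniformity"] == 1.0
        assert feats["run_entropy"] == 0.0

    def test_checkerboard_horizontal(self):
        cb = np.indices((4, 4)).sum(0) % 2
        m = glrlm_matrix(cb, np.ones((4, 4), bool), 0)
        assert sum(m.values()) == 16
        feats = glrlm_features(cb, np.ones((4, 4)), angles=(0,))
        assert feats["gray_level_nonuniformity"] == pytest.approx(8.0)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_run_conservation(self, rng, angle):
        levels = rng.integers(0, 6, (17, 13))
        mask = rng.random((17, 13)) > 0.3
        counts = glrlm_matrix(levels, mask, angle)
        assert sum(length * c for (_, length), c in counts.items()) == mask.sum()

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_brute_force_oracle(self, rng, angle):
        levels = rng.integers(0, 5, (12, 15))
        mask = rng.random((12, 15)) > 0.25
        assert glrlm_matrix(levels, mask, angle) == glrlm_brute_force(levels, mask, angle)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            glrlm_features(np.zeros((4, 4), int), np.zeros((4, 4)))


class TestFrameSelection:
    def masks_with_cavity_areas(self, areas):
        masks = []
        for a in areas:
            m = np.zeros((30, 30), dtype=np.uint8)
            m.ravel()[:a] = CAVITY
            masks.append(m)
        return masks

    def test_ed_es_extrema(self):
        masks = self.masks_with_cavity_areas([50, 80, 100, 60, 20, 40])
        i_ed, i_es, i_mid, amb = select_frames_ed_es_mid(masks)
        assert (i_ed, i_es) == (2, 4)
        assert i_mid == 3
        assert not amb

    def test_floor_rule(self):
        masks = self.masks_with_cavity_areas([100] + [90] * 10 + [10] + [50] * 3)
        i_ed, i_es, i_mid, _ = select_frames_ed_es_mid(masks)
        assert (i_ed, i_es) == (0, 11)
        assert i_mid == 5  # floor((0 + 11) / 2)

    def test_all_equal_is_ambiguous(self):
        masks = self.masks_with_cavity_areas([40] * 5)
        _, _, _, amb = select_frames_ed_es_mid(masks)
        assert amb

    def test_phantom_ed_is_max_area_frame(self, scar_study):
        i_ed, i_es, _, _ = select_frames_ed_es_mid(scar_study.masks)
        areas = [np.sum(m == CAVITY) for m in scar_study.masks]
        assert areas[i_ed] == max(areas)
        assert areas[i_es] == min(areas)


class TestFilters:
    def table(self, rng, n=200):
        data = {
            "col_a": rng.normal(0, 1, n),
            "col_b": rng.normal(0, 1, n),
            "col_d": rng.normal(0, 1, n),
        }
        return pd.DataFrame(data)

    def test_duplicate_column_dropped(self, rng):
        df = self.table(rng)
        df["col_c"] = df["col_a"]
        sel = redundancy_filter(df)
        assert "col_a" in sel.kept_names
        assert "col_c" not in sel.kept_names
        assert sel.dropped["col_c"]["partner"] == "col_a"

    def test_independent_columns_kept(self, rng):
        sel = redundancy_filter(self.table(rng))
        assert len(sel.kept_names) == 3

    def test_near_collinear_dropped_with_partner(self, rng):
        df = self.table(rng)
        df["col_c"] = df["col_a"] + rng.normal(0, 0.01, len(df))
        sel = redundancy_filter(df)
        assert "col_c" not in sel.kept_names
        assert sel.dropped["col_c"]["partner"] == "col_a"
        assert sel.dropped["col_c"]["r"] > 0.99

    def test_constant_column_reason(self, rng):
        df = self.table(rng)
        df["col_const"] = 1.0
        sel = redundancy_filter(df)
        assert sel.dropped["col_const"]["reason"] == "constant"

    def test_label_correlated_feature_kept(self, rng):
        y = np.repeat([0, 1], 50)
        df = pd.DataFrame({"good": y + rng.normal(0, 0.01, 100)})
        sel = significance_filter(df, y)
        assert "good" in sel.kept_names

    def test_noise_feature_dropped(self, rng):
        y = np.repeat([0, 1], 50)
        df = pd.DataFrame({f"noise{i}": rng.normal(0, 1, 100) for i in range(5)})
        sel = significance_filter(df, y)
        assert len(sel.kept_names) == 0

    def test_constant_feature_zero_variance_reason(self, rng):
        y = np.repeat([0, 1], 10)
        df = pd.DataFrame({"const": np.ones(20)})
        sel = significance_filter(df, y)
        assert sel.dropped["const"]["reason"] == "zero variance"

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            significance_filter(pd.DataFrame({"a": rng.normal(0, 1, 10)}), np.zeros(10))

    def test_composition_keeps_no_correlated_pair(self, rng):
        n = 150
        base = rng.normal(0, 1, n)
        y = (base + rng.normal(0, 0.5, n) > 0).astype(int)
        df = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(0, 0.01, n),
                "c": rng.normal(0, 1, n),
                "d": base * 0.9 + rng.normal(0, 0.4, n),
            }
        )
        red = RedundancyFilter(0.9).fit(df)
        reduced = red.transform(df)
        sig = SignificanceFilter(0.05).fit(reduced, y)
        kept = sig.transform(reduced)
        cols = list(kept.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = np.corrcoef(kept[cols[i]], kept[cols[j]])[0, 1]
                assert abs(r) <= 0.9


def test_radiomics_row_is_bit_stable(scar_study):
    row1 = extract_radiomics_row(scar_study.cine, scar_study.masks)
    row2 = extract_radiomics_row(scar_study.cine, scar_study.masks)
    assert row1 == row2
    assert len(row1) == 3 * 18  # shape(5) + firstorder(9) + glrlm(4) per frame
    assert any(k.startswith("es_shape_") for k in row1)
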