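"""Feature extraction: brute-force oracles for texture and intensity,
analytic shape fixtures, catalogue closure, and scale-behavior properties."""

import math

import numpy as np
import pandas as pd
import pytest

from mitohicp import simgen
from mitohicp.features import (
    aggregate_image_profiles,
    cross_channel_corr,
    extract_features,
    glcm_texture,
    granularity_spectrum,
    intensity_descriptors,
    neighbor_metrics,
    radial_distribution,
    shape_descriptors,
)
from mitohicp.manifest import HARALICK_STATS, default_manifest
from skimage.morphology import disk


# ---------------------------------------------------------------- GLCM oracle

def oracle_haralick(image, mask, levels, offsets):
    """Independent Haralick oracle: explicit pair enumeration and plain-loop
    statistics over the averaged symmetric normalized co-occurrence matrix."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    H, W = image.shape
    q = {}
    for i in range(H):
        for j in range(W):
            if mask[i, j]:
                if hi > lo:
                    level = int((image[i, j] - lo) / (hi - lo) * levels)
                    q[(i, j)] = min(level, levels - 1)
                else:
                    q[(i, j)] = 0
    P = np.zeros((levels, levels))
    n_off = 0
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        for (i, j), a in q.items():
            other = (i + dr, j + dc)
            if other in q:
                b = q[other]
                counts[a, b] += 1
                counts[b, a] += 1
        if counts.sum() > 0:
            P += counts / counts.sum()
            n_off += 1
    P /= n_off

    L = levels
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))
    out = {}
    out["asm"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out["correlation"] = (
        sum((i - mu) * (j - mu) * P[i, j] for i in range(L) for j in range(L)) / var
        if var > 1e-12 else 0.0
    )
    out["variance"] = var
    out["idm"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    out["sum_avg"] = sum(k * psum[k] for k in range(2 * L - 1))
    out["sum_var"] = sum((k - out["sum_avg"]) ** 2 * psum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = -sum(p * math.log(p) for p in psum if p > 0)
    out["entropy"] = -sum(
        P[i, j] * math.log(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0
    )
    dmean = sum(k * pdiff[k] for k in range(L))
    out["diff_var"] = sum((k - dmean) ** 2 * pdiff[k] for k in range(L))
    out["diff_entropy"] = -sum(p * math.log(p) for p in pdiff if p > 0)
    hxy = out["entropy"]
    hx = -sum(p * math.log(p) for p in px if p > 0)
    hxy1 = -sum(
        P[i, j] * math.log(px[i] * px[j])
        for i in range(L) for j in range(L) if P[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log(px[i] * px[j])
        for i in range(L) for j in range(L) if px[i] * px[j] > 0
    )
    out["imc1"] = (hxy - hxy1) / hx if hx > 1e-12 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return out


class TestGlcmTexture:
    def test_constant_region_degenerate_conventions(self):
        img = np.full((10, 10), 5.0)
        mask = np.ones((10, 10), bool)
        f = glcm_texture(img, mask, levels=8, distance=1)
        assert f["contrast"] == 0.0
        assert f["idm"] == 1.0
        assert f["correlation"] == 0.0  # zero-variance convention
        assert f["asm"] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_random_patch_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, size=(16, 16))
        mask = rng.random((16, 16)) > 0.2
        if mask.sum() < 2:
            mask[:2, 0] = True
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
        got = glcm_texture(img, mask, levels=8, distance=1)
        want = oracle_haralick(img, mask, 8, offsets)
        for stat in HARALICK_STATS:
            assert got[stat] == pytest.approx(want[stat], abs=1e-10), stat

    def test_checkerboard_axial_asm(self):
        img = np.indices((8, 8)).sum(axis=0) % 2
        mask = np.ones((8, 8), bool)
        f = glcm_texture(img.astype(float), mask, levels=2, offsets=[(0, 1)])
        # all axial pairs alternate: P = [[0, .5], [.5, 0]] -> ASM = 0.5
        assert f["asm"] == pytest.approx(0.5, abs=1e-12)
        assert f["contrast"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_all_missing(self):
        f = glcm_texture(np.zeros((5, 5)), np.zeros((5, 5), bool))
        assert all(np.isnan(v) for v in f.values())

    def test_fixed_value_range_quantization(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(10, 20, (12, 12))
        mask = np.ones((12, 12), bool)
        # with a fixed range, rescaling the intensities changes the GLCM ...
        a = glcm_texture(img, mask, levels=8, value_range=(0.0, 40.0))
        b = glcm_texture(2 * img, mask, levels=8, value_range=(0.0, 40.0))
        assert a["contrast"] != pytest.approx(b["contrast"], abs=1e-6)
        # ... while the default per-object min-max stays invariant
        c = glcm_texture(2 * img, mask, levels=8)
        d = glcm_texture(img, mask, levels=8)
        assert c["contrast"] == pytest.approx(d["contrast"], abs=1e-10)

    def test_affine_intensity_rescale_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, size=(20, 20))
        mask = disk(8).astype(bool)
        pad = np.zeros((20, 20), bool)
        pad[1:18, 1:18] = mask
        a = glcm_texture(img, pad)
        b = glcm_texture(3.5 * img + 11.0, pad)
        for stat in HARALICK_STATS:
            assert a[stat] == pytest.approx(b[stat], abs=1e-9), stat


class TestShapeDescriptors:
    def test_digital_disc(self):
        f = shape_descriptors(disk(10).astype(bool))
        assert f["area"] == pytest.approx(100 * np.pi, rel=0.02)
        assert 0.85 <= f["form_factor"] <= 1.05
        assert f["eccentricity"] < 0.1

    def test_rectangle_moments(self):
        mask = np.zeros((14, 24), bool)
        mask[2:12, 2:22] = True
        f = shape_descriptors(mask)
        assert f["area"] == 200
        assert f["extent"] == 1.0
        assert f["aspect_ratio"] == pytest.approx(2.0, rel=0.05)
        assert f["bbox_width"] == 20 and f["bbox_height"] == 10

    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        f = shape_descriptors(mask)
        assert f["area"] == 1 and f["euler_number"] == 1

    def test_empty_mask_missing(self):
        f = shape_descriptors(np.zeros((4, 4), bool))
        assert all(np.isnan(v) for v in f.values())


class TestIntensityDescriptors:
    def test_uniform_region(self):
        mask = np.ones((5, 5), bool)
        f = intensity_descriptors(np.full((5, 5), 7.0), mask)
        assert f["mean"] == f["median"] == f["min"] == f["max"] == 7.0
        assert f["sd"] == 0.0 and f["integrated"] == 175.0

    def test_listed_values_match_sort_oracle(self):
        img = np.array([[3., 1., 4.], [1., 5., 9.], [2., 6., 5.]])
        f = intensity_descriptors(img, np.ones((3, 3), bool))
        # quantiles frozen from the sorted-list interpolation formula
        assert f["q05"] == pytest.approx(1.0)
        assert f["q25"] == pytest.approx(2.0)
        assert f["q75"] == pytest.approx(5.0)
        assert f["q95"] == pytest.approx(7.8)
        assert f["median"] == 4.0 and f["mad"] == 2.0

    def test_empty_mask_missing(self):
        f = intensity_descriptors(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert all(np.isnan(v) for v in f.values())

    def test_linear_in_global_rescale(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 50, (9, 9))
        mask = rng.random((9, 9)) > 0.3
        a = intensity_descriptors(img, mask)
        b = intensity_descriptors(4.0 * img, mask)
        for stat in ("mean", "median", "sd", "mad", "min", "max", "integrated",
                     "q05", "q25", "q75", "q95", "edge_mean"):
            assert b[stat] == pytest.approx(4.0 * a[stat], rel=1e-12)
        assert b["mass_disp"] == pytest.approx(a["mass_disp"], rel=1e-12)


class TestCrossChannelCorr:
    def test_proportional_channels(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 10, (6, 6))
        mask = np.ones((6, 6), bool)
        f = cross_channel_corr(a, 2 * a, mask)
        assert f["pcc"] == pytest.approx(1.0)

    def test_anticorrelated_channels(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 10, (6, 6))
        f = cross_channel_corr(a, -a + 20, np.ones((6, 6), bool))
        assert f["pcc"] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 5, (5, 5))
        b = rng.uniform(0, 5, (5, 5))
        mask = rng.random((5, 5)) > 0.3
        f = cross_channel_corr(a, b, mask)
        x, y = a[mask], b[mask]
        n = x.size
        pcc = (n * (x * y).sum() - x.sum() * y.sum()) / math.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert f["pcc"] == pytest.approx(pcc, abs=1e-12)
        assert f["overlap"] == pytest.approx(
            (x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum()), abs=1e-12)
        assert f["manders"] == pytest.approx(x[y > 0].sum() / x.sum(), abs=1e-12)

    def test_zero_variance_pcc_missing(self):
        f = cross_channel_corr(np.ones((4, 4)), np.arange(16.0).reshape(4, 4),
                               np.ones((4, 4), bool))
        assert np.isnan(f["pcc"]) and not np.isnan(f["overlap"])


class TestGranularity:
    def test_uniform_disc_spectrum(self):
        img = np.zeros((30, 30))
        mask = np.zeros((30, 30), bool)
        mask[8:21, 8:21] = disk(6).astype(bool)
        img[mask] = 5.0
        g = granularity_spectrum(img, mask)
        assert sum(g.values()) == pytest.approx(1.0, abs=1e-9)
        # a uniform disc survives openings smaller than its radius ...
        assert sum(g[r] for r in range(1, 5)) < 0.1
        # ... and is entirely removed soon after the radius is exceeded
        assert sum(g[r] for r in range(1, 9)) > 0.95

    def test_empty_mask_missing(self):
        g = granularity_spectrum(np.ones((8, 8)), np.zeros((8, 8), bool))
        assert all(np.isnan(v) for v in g.values())


class TestRadialAndNeighbors:
    def test_innermost_concentration(self):
        mask = np.zeros((41, 41), bool)
        mask[20 - 15:20 + 16, 20 - 15:20 + 16] = disk(15).astype(bool)
        img = np.zeros((41, 41))
        inner = np.zeros((41, 41), bool)
        inner[20 - 4:20 + 5, 20 - 4:20 + 5] = disk(4).astype(bool)
        img[inner] = 10.0
        f = radial_distribution(img, mask, center=(20, 20))
        assert f["frac_at_d_b1"] == pytest.approx(1.0)
        for b in (2, 3, 4):
            assert f[f"frac_at_d_b{b}"] == pytest.approx(0.0, abs=1e-12)

    def test_isolated_object_has_no_neighbors(self):
        labels = np.zeros((32, 32), np.int32)
        labels[10:20, 10:20] = 1
        t = neighbor_metrics(labels)
        assert t["n_neighbors"].iloc[0] == 0
        assert t["percent_touching"].iloc[0] == 0
        assert np.isnan(t["dist1"].iloc[0])

    def test_touching_pair(self):
        labels = np.zeros((32, 32), np.int32)
        labels[10:20, 5:15] = 1
        labels[10:20, 15:25] = 2
        t = neighbor_metrics(labels).set_index("label")
        assert t.loc[1, "n_neighbors"] == 1
        assert t.loc[1, "percent_touching"] > 0
        assert t.loc[1, "dist1"] == pytest.approx(10.0)


class TestExtractFeatures:
    def test_default_manifest_yields_541_columns(self, segmented_field):
        stack, _, maps = segmented_field
        m = default_manifest()
        t = extract_features(stack, maps, m)
        assert list(t.columns) == ["cell_id"] + m.names
        assert len(t.columns) - 1 == 541

    def test_shape_family_manifest_yields_45_columns(self, segmented_field):
        stack, _, maps = segmented_field
        m = default_manifest().subset(families=["shape"])
        t = extract_features(stack, maps, m)
        assert len(t.columns) - 1 == 45
        assert list(t.columns)[1:] == m.names

    def test_empty_field_keeps_full_header(self, compact_geometry):
        stack, gt = simgen.render_field(
            pd.DataFrame(columns=["cell_id", "M", "R", "S"]), compact_geometry, seed=1
        )
        m = default_manifest()
        t = extract_features(stack, {"nuclei": gt.nuclei, "cells": gt.cells,
                                     "mito": gt.mito}, m)
        assert len(t) == 0
        assert list(t.columns) == ["cell_id"] + m.names

    def test_subset_order_preserved(self, segmented_field):
        stack, _, maps = segmented_field
        m = default_manifest()
        names = [m.names[i] for i in (5, 100, 300, 500)]
        sub = m.subset(names=names)
        t = extract_features(stack, maps, sub)
        assert list(t.columns)[1:] == sub.names


def test_shipped_manifest_matches_builtin_catalogue():
    from mitohicp.manifest import FeatureManifest, shipped_manifest_path

    shipped = FeatureManifest.from_csv(shipped_manifest_path())
    builtin = default_manifest()
    assert shipped.names == builtin.names
    pd.testing.assert_frame_equal(shipped.table, builtin.table)


class TestAggregateProfiles:
    def test_mean_of_two_cells(self):
        t = pd.DataFrame({"well": "A1", "field": 0, "cell_id": [1, 2],
                          "f": [1.0, 3.0]})
        p = aggregate_image_profiles(t, feature_names=["f"])
        assert p["f"].iloc[0] == 2.0
        assert p["n_cells"].iloc[0] == 2

    def test_missing_values_skipped(self):
        t = pd.DataFrame({"well": "A1", "field": 0, "cell_id": [1, 2, 3],
                          "f": [1.0, np.nan, 3.0]})
        p = aggregate_image_profiles(t, feature_names=["f"])
        assert p["f"].iloc[0] == 2.0

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({
            "well": np.repeat(["A1", "A2"], 10), "field": 0,
            "cell_id": np.tile(np.arange(10), 2),
            "f1": rng.normal(size=20), "f2": rng.normal(size=20),
        })
        p = aggregate_image_profiles(t, feature_names=["f1", "f2"]).set_index("well")
        for well in ("A1", "A2"):
            sub = t[t.well == well]
            assert float(p.loc[well, "f1"]) == pytest.approx(sub["f1"].mean())

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate_image_profiles(pd.DataFrame())
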