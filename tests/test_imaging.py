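"""Droplet segmentation, enrichment scoring and colocalization, verified
against planted ground truth."""

import numpy as np
import pytest

from rg4fus.imaging import (count_assemblies, cytoplasmic_foci_mask,
                            enhance_speckles, enrichment_scores,
                            pearson_colocalization, phase_diagram,
                            segment_droplets)
from rg4fus.simulate import simulate_cell_image, simulate_droplet_image


class TestSegmentation:
    def test_recovers_planted_disks(self):
        grid, truth, disks = simulate_droplet_image(n_droplets=7, seed=3)
        labels, records = segment_droplets(grid, threshold=150.0)
        assert len(records) == 7
        planted_areas = sorted(np.pi * r * r for _, _, r in disks)
        found_areas = sorted(rec.area_px for rec in records)
        for planted, found in zip(planted_areas, found_areas):
            assert abs(found - planted) / planted < 0.10

    def test_uniform_image_zero_droplets(self):
        grid = np.full((32, 32), 5.0)
        labels, records = segment_droplets(grid, threshold="otsu")
        assert records == [] and labels.max() == 0

    def test_one_pixel_bridge_merges_components(self):
        grid = np.zeros((32, 32))
        grid[8:14, 8:14] = 10.0
        grid[8:14, 16:22] = 10.0
        grid[10, 14] = 10.0
        grid[10, 15] = 10.0
        _, records = segment_droplets(grid, threshold=5.0)
        assert len(records) == 1  # 8-connectivity joins via the bridge

    def test_min_area_filters_specks(self):
        grid = np.zeros((32, 32))
        grid[5, 5] = 10.0            # 1 px — discarded
        grid[20:24, 20:24] = 10.0    # 16 px — kept
        _, records = segment_droplets(grid, threshold=5.0, min_area=4)
        assert len(records) == 1


class TestEnrichment:
    def test_planted_partition_ratio(self):
        grid, truth, _ = simulate_droplet_image(inside=200.0,
                                                background=100.0, sigma=0.0,
                                                seed=1)
        scores = enrichment_scores(grid, truth)
        assert scores and all(abs(s - 2.0) < 0.05 for s in scores)

    def test_equal_intensity_gives_one(self):
        grid = np.full((32, 32), 7.0)
        labels = np.zeros((32, 32), dtype=int)
        labels[10:14, 10:14] = 1
        assert enrichment_scores(grid, labels) == [pytest.approx(1.0)]

    def test_scale_invariance(self):
        grid, truth, _ = simulate_droplet_image(seed=2)
        a = enrichment_scores(grid, truth)
        b = enrichment_scores(2.5 * grid, truth)
        assert np.allclose(a, b)

    def test_halo_pixels_excluded_from_background(self):
        grid = np.full((64, 64), 100.0)
        labels = np.zeros((64, 64), dtype=int)
        labels[30:34, 30:34] = 1
        grid[30:34, 30:34] = 200.0
        # sentinel intensity on the 2-px Euclidean halo around the droplet
        yy, xx = np.mgrid[0:64, 0:64]
        fg_y, fg_x = np.nonzero(labels)
        dist2 = np.min((yy[..., None] - fg_y) ** 2 + (xx[..., None] - fg_x) ** 2,
                       axis=-1)
        ring = (dist2 <= 4) & (labels == 0)
        grid[ring] = 10_000.0
        (score,) = enrichment_scores(grid, labels, halo_px=2)
        assert score == pytest.approx(2.0, abs=0.01)


class TestPhaseDiagram:
    def test_mean_count_and_empty_cell(self):
        import pandas as pd
        rows = [{"condition": "S1", "time": 60, "image": i, "count": 3,
                 "enrichment": 2.0} for i in range(10)]
        rows.append({"condition": "S1", "time": 120, "image": 0, "count": 0,
                     "enrichment": np.nan})
        out = phase_diagram(pd.DataFrame(rows)).set_index("time")
        assert out.loc[60, "mean_count"] == pytest.approx(3.0)
        assert out.loc[120, "mean_count"] == 0.0
        assert np.isnan(out.loc[120, "mean_enrichment"])

    def test_planted_concentration_series_is_monotone(self):
        import pandas as pd
        rows = []
        for conc, n in ((0, 9), (1, 6), (8, 3), (32, 0)):
            grid, _, _ = simulate_droplet_image(n_droplets=n, seed=conc + 10)
            _, records = segment_droplets(grid, threshold=150.0)
            rows.append({"condition": conc, "time": 60, "image": 0,
                         "count": len(records)})
        out = phase_diagram(pd.DataFrame(rows)).sort_values("condition")
        counts = out["mean_count"].tolist()
        assert counts == sorted(counts, reverse=True)


class TestSpeckleEnhancement:
    def test_flat_image_to_zero(self):
        assert np.allclose(enhance_speckles(np.full((64, 64), 9.0)), 0.0)

    def test_small_dot_preserved_background_removed(self):
        grid = np.full((64, 64), 50.0)
        grid[30:33, 30:33] = 250.0
        out = enhance_speckles(grid, feature_size=20)
        assert out[31, 31] == pytest.approx(200.0)
        assert out[5, 5] == pytest.approx(0.0)

    def test_gradient_suppressed_dots_retained(self):
        yy, xx = np.mgrid[0:128, 0:128]
        gradient = 100.0 * xx / 127.0
        grid = gradient.copy()
        dots = np.zeros((128, 128), dtype=bool)
        for cy, cx in ((20, 20), (60, 90), (100, 40)):
            dots[cy - 2:cy + 3, cx - 2:cx + 3] = True
        grid[dots] += 150.0
        out = enhance_speckles(grid, feature_size=20)
        assert out[~dots].mean() < 0.1 * gradient.mean()
        assert np.corrcoef(out.ravel(), dots.ravel().astype(float))[0, 1] > 0.8


class TestColocalization:
    def test_identity_and_inversion(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 100, (32, 32))
        mask = np.ones((32, 32), dtype=bool)
        assert pearson_colocalization(a, a, mask) == pytest.approx(1.0)
        assert pearson_colocalization(a, 200 - a, mask) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(10, 100, (32, 32))
        b = rng.uniform(10, 100, (32, 32))
        mask = np.ones((32, 32), dtype=bool)
        r1 = pearson_colocalization(a, b, mask)
        r2 = pearson_colocalization(3 * a + 7, 0.5 * b + 1, mask)
        assert r1 == pytest.approx(r2)

    def test_increases_with_shared_foci_fraction(self):
        rs = []
        for f in (0.0, 0.5, 1.0):
            imgs = simulate_cell_image(shared_fraction=f, seed=8)
            mask_a = cytoplasmic_foci_mask(imgs["a"], imgs["nuclei"])
            mask_b = cytoplasmic_foci_mask(imgs["b"], imgs["nuclei"])
            rs.append(pearson_colocalization(imgs["a"], imgs["b"],
                                             mask_a | mask_b))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.8

    def test_small_mask_rejected(self):
        a = np.random.default_rng(0).uniform(1, 2, (32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[0, :5] = True
        with pytest.raises(ValueError):
            pearson_colocalization(a, a, mask)


class TestCytoplasmicMask:
    def test_recovers_planted_cytoplasmic_foci(self):
        imgs = simulate_cell_image(seed=12)
        mask = cytoplasmic_foci_mask(imgs["a"], imgs["nuclei"])
        truth = imgs["truth_cyto_a"]
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.7

    def test_no_nuclei_mask_equals_foci(self):
        imgs = simulate_cell_image(seed=13)
        flat_nuclei = np.full(imgs["a"].shape, 5.0)
        with_nuclei = cytoplasmic_foci_mask(imgs["a"], imgs["nuclei"])
        without = cytoplasmic_foci_mask(imgs["a"], flat_nuclei)
        # removing nuclei can only grow the mask
        assert (with_nuclei & ~without).sum() == 0
        assert without.sum() >= with_nuclei.sum()

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            cytoplasmic_foci_mask(np.zeros((32, 32)), np.zeros((64, 64)))


class TestCountAssemblies:
    def test_means(self):
        def lm(n):
            m = np.zeros((16, 16), dtype=int)
            for i in range(n):
                m[i, i] = i + 1
            return m
        assert count_assemblies([lm(0), lm(0), lm(0)]) == 0.0
        assert count_assemblies([lm(2), lm(4)]) == 3.0

    def test_poisson_scale_recovery(self):
        counts = []
        for seed in range(6):
            grid, _, _ = simulate_droplet_image(n_droplets=9, seed=seed)
            labels, _ = segment_droplets(grid, threshold=150.0)
            counts.append(labels)
        assert count_assemblies(counts) == pytest.approx(9.0, abs=1.0)
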